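"""Genome records: contig sequences plus masked-interval bookkeeping.

A :class:`GenomeRecord` is the unit handled by every stage: the simulator
produces them, the mapper concatenates them into a reference, and the
taxonomy indices compare them pairwise.  Masked intervals mark regions
(typically ribosomal-operon analogues) that are excluded from coverage
denominators because near-identical repeats shared between species attract
cross-mapping reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

_BASES = b"ACGT"
_BASE_ARR = np.frombuffer(_BASES, dtype=np.uint8)

# uint8 byte value -> base index 0..3, 255 for anything else
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[_b] = _i

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array of base indices 0..3."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = sorted(set(seq) - set("ACGT"))
        raise DataError(f"sequence contains non-ACGT symbols: {bad}")
    return arr


def codes_to_seq(codes: np.ndarray) -> str:
    """Decode a base-index array back to a string."""
    return _BASE_ARR[codes].tobytes().decode("ascii")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Normalize (contig, start, end) half-open intervals: sort and merge overlaps."""
    merged: list[tuple[int, int, int]] = []
    for civ in sorted(intervals):
        c, s, e = civ
        if s >= e:
            continue
        if merged and merged[-1][0] == c and s <= merged[-1][2]:
            pc, ps, pe = merged[-1]
            merged[-1] = (pc, ps, max(pe, e))
        else:
            merged.append((c, s, e))
    return merged


@dataclass
class GenomeRecord:
    """A (draft) genome: one or more contigs plus masked intervals.

    Parameters
    ----------
    genome_id : str
        Unique identifier (FASTA record prefix).
    contigs : list of str
        Nucleotide sequences over {A, C, G, T}.
    masked_intervals : list of (contig_index, start, end)
        0-based half-open intervals excluded from coverage denominators.
    """

    genome_id: str
    contigs: list[str]
    masked_intervals: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise DataError(f"genome {self.genome_id!r} has no contigs")
        self.masked_intervals = merge_intervals(self.masked_intervals)
        for c, s, e in self.masked_intervals:
            if not (0 <= c < len(self.contigs)):
                raise DataError(
                    f"genome {self.genome_id!r}: mask references contig {c} "
                    f"but only {len(self.contigs)} contigs exist"
                )
            if not (0 <= s < e <= len(self.contigs[c])):
                raise DataError(
                    f"genome {self.genome_id!r}: mask [{s},{e}) outside contig {c} "
                    f"of length {len(self.contigs[c])}"
                )

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.contigs)

    @property
    def masked_length(self) -> int:
        return sum(e - s for _, s, e in self.masked_intervals)

    @property
    def gc_fraction(self) -> float:
        """Empirical G+C fraction of the full sequence."""
        gc = sum(c.count("G") + c.count("C") for c in self.contigs)
        return gc / self.total_length

    def contig_codes(self) -> list[np.ndarray]:
        return [seq_to_codes(c) for c in self.contigs]
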