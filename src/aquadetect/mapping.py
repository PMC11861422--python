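"""Read placement on a concatenated masked reference, and per-base coverage.

The reference is the concatenation of all genomes (all contigs, in order),
with masked intervals (ribosomal-operon analogues) excluded from every
breadth/depth denominator but left in the sequence, mirroring how a set of
type-strain genomes is screened against a metagenome.

The internal mapper is deliberately simple: exact k-mer seeds taken from
both ends of the read on both strands, ungapped extension over the full read
length, and a post-hoc identity filter (default 95%, the species demarcation
threshold).  A read is reported at most once, at its best-identity locus;
ties are broken by the lowest global reference coordinate.  Alignments from
an external mapper can be substituted via SAM (:func:`import_alignments`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pysam

from .errors import DataError, MemberLookupError, ParameterError
from .genomes import GenomeRecord, reverse_complement, seq_to_codes
from .synthetic import ReadSet

logger = logging.getLogger(__name__)

SAM_NAME_SEP = "|"


def sam_reference_name(genome_id: str, contig_index: int) -> str:
    return f"{genome_id}{SAM_NAME_SEP}{contig_index}"


@dataclass
class AlignmentRecord:
    """One placed read: ungapped span on a single contig."""

    read_id: str
    genome_id: str
    contig_index: int
    start: int  # 0-based, forward reference coordinates
    aligned_length: int
    matches: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.aligned_length


@dataclass
class CoverageProfile:
    """Per-genome coverage summary over unmasked positions."""

    genome_id: str
    depth_vector: np.ndarray  # depth at each unmasked position
    breadth_pct: float
    mean_depth: float
    mapped_reads: int
    mapped_read_pct: float


class ReferenceSet:
    """Concatenated genomes with per-genome masks and coordinate maps.

    Global coordinates run over all contigs of all genomes in order; they
    map bijectively to (genome, contig, position).
    """

    def __init__(self, genomes: list[GenomeRecord]):
        ids = [g.genome_id for g in genomes]
        if len(set(ids)) != len(ids):
            raise DataError("genome ids must be unique")
        if not genomes:
            raise DataError("reference needs at least one genome")
        self.genomes = list(genomes)
        self.genome_ids = ids
        self._index = {gid: i for i, gid in enumerate(ids)}

        self.contig_offsets: list[np.ndarray] = []  # within-genome start of each contig
        self.offsets = np.zeros(len(genomes), dtype=np.int64)  # global start per genome
        segments = []  # (global_start, genome_idx, contig_idx, length)
        gpos = 0
        for gi, g in enumerate(genomes):
            self.offsets[gi] = gpos
            lens = np.array([len(c) for c in g.contigs], dtype=np.int64)
            self.contig_offsets.append(np.concatenate([[0], np.cumsum(lens)[:-1]]))
            for ci, ln in enumerate(lens):
                segments.append((gpos, gi, ci, int(ln)))
                gpos += int(ln)
        self.total_length = gpos
        self.segment_starts = np.array([s[0] for s in segments], dtype=np.int64)
        self.segments = segments

        self.seq_codes = np.concatenate([seq_to_codes(c) for g in genomes for c in g.contigs])

        # genome-level boolean masks (True = masked) over concatenated contigs
        self.masks: list[np.ndarray] = []
        for gi, g in enumerate(genomes):
            m = np.zeros(g.total_length, dtype=bool)
            for ci, s, e in g.masked_intervals:
                off = int(self.contig_offsets[gi][ci])
                m[off + s: off + e] = True
            self.masks.append(m)
        self.unmasked_length = np.array([int((~m).sum()) for m in self.masks])

    def genome_index(self, genome_id: str) -> int:
        try:
            return self._index[genome_id]
        except KeyError:
            raise MemberLookupError(f"unknown genome id {genome_id!r}") from None

    def locate(self, global_pos: int) -> tuple[int, int, int]:
        """Map a global coordinate to (genome_index, contig_index, position)."""
        if not (0 <= global_pos < self.total_length):
            raise DataError(f"global position {global_pos} out of range")
        si = int(np.searchsorted(self.segment_starts, global_pos, side="right")) - 1
        start, gi, ci, _ = self.segments[si]
        return gi, ci, global_pos - start

    def segment_of(self, global_pos: int) -> tuple[int, int, int, int]:
        """Segment (global_start, genome_idx, contig_idx, length) containing a position."""
        si = int(np.searchsorted(self.segment_starts, global_pos, side="right")) - 1
        return self.segments[si]


def build_reference(
    genomes: list[GenomeRecord],
    masks: list[tuple[str, int, int, int]] | None = None,
) -> ReferenceSet:
    """Assemble a :class:`ReferenceSet`, merging extra masks into the genomes.

    ``masks`` entries are (genome_id, contig_index, start, end), 0-based
    half-open — e.g. parsed from a BED file whose chromosome names follow the
    ``genomeid|contigindex`` dialect.  Masked positions are excluded from
    ``unmasked_length`` and from all breadth/depth denominators.
    """
    if masks:
        by_id = {g.genome_id: g for g in genomes}
        extra: dict[str, list[tuple[int, int, int]]] = {}
        for gid, ci, s, e in masks:
            if gid not in by_id:
                raise MemberLookupError(f"mask references unknown genome {gid!r}")
            extra.setdefault(gid, []).append((ci, s, e))
        genomes = [
            GenomeRecord(
                g.genome_id,
                list(g.contigs),
                list(g.masked_intervals) + extra.get(g.genome_id, []),
            )
            for g in genomes
        ]
    return ReferenceSet(genomes)


class _SeedIndex:
    """Exact k-mer index over the concatenated reference (forward strand)."""

    def __init__(self, ref: ReferenceSet, k: int):
        self.k = k
        self.index: dict[bytes, list[int]] = {}
        raw = ref.seq_codes.tobytes()
        for gstart, _gi, _ci, ln in ref.segments:
            for pos in range(gstart, gstart + ln - k + 1):
                kmer = raw[pos: pos + k]
                self.index.setdefault(kmer, []).append(pos)

    def lookup(self, kmer_codes: np.ndarray) -> list[int]:
        return self.index.get(kmer_codes.tobytes(), [])


def map_reads(
    reads: ReadSet,
    ref: ReferenceSet,
    min_identity_pct: float = 95.0,
    k: int = 31,
    max_candidates: int = 64,
) -> list[AlignmentRecord]:
    """Seed-and-extend placement of reads at >= ``min_identity_pct`` identity.

    One exact k-mer seed is taken from each end of the read, on both strands;
    every seeded locus is scored by ungapped comparison over the full read
    length, and the best-identity locus (ties: lowest global coordinate) is
    reported if it clears the identity filter.
    """
    if not reads.reads:
        raise ParameterError("read set is empty")
    if not (0 < min_identity_pct <= 100):
        raise ParameterError("min_identity_pct must be in (0, 100]")
    if ref.total_length == 0:
        raise DataError("reference is empty")

    seed_index = _SeedIndex(ref, k)
    out: list[AlignmentRecord] = []
    for read in reads.reads:
        L = len(read.sequence)
        if L < k:
            continue
        candidates: list[tuple[int, int]] = []  # (global_start, strand 0=+ 1=-)
        seen = set()
        for strand, seq in ((0, read.sequence), (1, reverse_complement(read.sequence))):
            codes = seq_to_codes(seq)
            for off in (0, L - k):
                for gpos in seed_index.lookup(codes[off: off + k]):
                    g0 = gpos - off
                    key = (g0, strand)
                    if key not in seen:
                        seen.add(key)
                        candidates.append(key)
                    if len(candidates) >= max_candidates:
                        break
        if not candidates:
            continue
        # lowest global coordinate wins ties; prefer forward strand on exact ties
        candidates.sort()
        best: tuple[int, int, int] | None = None  # (matches, g0, strand)
        fwd = seq_to_codes(read.sequence)
        rev = seq_to_codes(reverse_complement(read.sequence))
        for g0, strand in candidates:
            if g0 < 0:
                continue
            seg_start, gi, ci, seg_len = ref.segment_of(min(g0, ref.total_length - 1))
            if g0 < seg_start or g0 + L > seg_start + seg_len:
                continue  # read would cross a contig boundary
            q = rev if strand else fwd
            matches = int((q == ref.seq_codes[g0: g0 + L]).sum())
            if best is None or matches > best[0]:
                best = (matches, g0, strand)
        if best is None:
            continue
        matches, g0, _strand = best
        if 100.0 * matches / L < min_identity_pct:
            continue
        gi, ci, pos = ref.locate(g0)
        out.append(
            AlignmentRecord(
                read_id=read.read_id,
                genome_id=ref.genome_ids[gi],
                contig_index=ci,
                start=pos,
                aligned_length=L,
                matches=matches,
            )
        )
    return out


def import_alignments(
    sam_source,
    ref: ReferenceSet,
    min_identity_pct: float = 95.0,
) -> list[AlignmentRecord]:
    """Ingest alignments from SAM produced by an external mapper.

    Reference sequence names must follow the ``genomeid|contigindex``
    dialect.  Identity is ``100*(aligned_length - NM)/aligned_length`` using
    the NM tag, or mismatch counting via the MD tag when NM is absent;
    records with neither are skipped with a warning.  Unmapped, secondary
    and supplementary records are ignored.  pysam converts SAM's 1-based
    coordinates to the package's 0-based convention.
    """
    n_skipped = 0
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(sam_source, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.reference_name
            if name is None or SAM_NAME_SEP not in name:
                raise DataError(f"SAM reference name {name!r} not in 'genomeid|contigindex' form")
            gid, ci_str = name.rsplit(SAM_NAME_SEP, 1)
            gi = ref.genome_index(gid)
            ci = int(ci_str)
            alen = rec.query_alignment_length
            if alen == 0:
                continue
            if rec.has_tag("NM"):
                nm = int(rec.get_tag("NM"))
            elif rec.has_tag("MD"):
                pairs = rec.get_aligned_pairs(with_seq=True)
                nm = sum(1 for _q, _r, s in pairs if s is not None and s.islower())
                nm += sum(1 for q, r, _s in pairs if q is None or r is None)
            else:
                n_skipped += 1
                logger.warning("SAM record %s lacks NM and MD tags; skipped", rec.query_name)
                continue
            matches = alen - nm
            if 100.0 * matches / alen < min_identity_pct:
                continue
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    genome_id=gid,
                    contig_index=ci,
                    start=rec.reference_start,
                    aligned_length=alen,
                    matches=matches,
                )
            )
    if n_skipped:
        logger.warning("%d SAM records skipped (no NM/MD tag)", n_skipped)
    return out


def compute_coverage(
    alignments: list[AlignmentRecord],
    ref: ReferenceSet,
    total_reads: int,
    min_depth_for_breadth: int = 1,
) -> list[CoverageProfile]:
    """Per-genome breadth, mean depth and mapped-read fraction.

    Depth is accumulated over aligned spans intersected with unmasked
    positions; breadth is the percentage of unmasked positions with depth >=
    ``min_depth_for_breadth``; ``mapped_read_pct`` uses the total read count
    of the metagenome (pre-mapping) as denominator.
    """
    if total_reads < len({a.read_id for a in alignments}):
        raise ParameterError("total_reads smaller than the number of aligned reads")
    diffs = [np.zeros(g.total_length + 1, dtype=np.int64) for g in ref.genomes]
    counts = np.zeros(len(ref.genomes), dtype=np.int64)
    for a in alignments:
        gi = ref.genome_index(a.genome_id)
        off = int(ref.contig_offsets[gi][a.contig_index])
        clen = len(ref.genomes[gi].contigs[a.contig_index])
        if a.start < 0 or a.start + a.aligned_length > clen:
            raise DataError(
                f"alignment of {a.read_id!r} outside contig bounds "
                f"({a.start}+{a.aligned_length} on {clen} bp)"
            )
        diffs[gi][off + a.start] += 1
        diffs[gi][off + a.start + a.aligned_length] -= 1
        counts[gi] += 1

    profiles = []
    for gi, g in enumerate(ref.genomes):
        depth = np.cumsum(diffs[gi][:-1])
        unmasked = depth[~ref.masks[gi]]
        ulen = int(ref.unmasked_length[gi])
        if ulen == 0:
            warnings.warn(
                f"genome {g.genome_id!r} is fully masked; breadth reported as 0",
                stacklevel=2,
            )
            breadth = 0.0
            mean_depth = 0.0
        else:
            breadth = 100.0 * float((unmasked >= min_depth_for_breadth).sum()) / ulen
            mean_depth = float(unmasked.sum()) / ulen
        profiles.append(
            CoverageProfile(
                genome_id=g.genome_id,
                depth_vector=unmasked,
                breadth_pct=breadth,
                mean_depth=mean_depth,
                mapped_reads=int(counts[gi]),
                mapped_read_pct=100.0 * float(counts[gi]) / total_reads if total_reads else 0.0,
            )
        )
    return profiles
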