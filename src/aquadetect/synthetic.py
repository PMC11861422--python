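"""Synthetic communities: genomes, divergent relatives, shared repeats, reads.

The generator emulates the statistical structure that the detection and
taxonomy stages assume about real freshwater metagenomes:

* genomes are i.i.d. base sequences at a controlled G+C fraction;
* related species are produced by per-site substitution at a chosen rate,
  so a rate-``r`` relative has expected nucleotide identity ``100*(1-r)`` %;
* near-identical repeats (ribosomal-operon analogues) can be planted into
  every genome, with their coordinates recorded as masked intervals;
* shotgun reads follow the Lander-Waterman model: read origins are drawn
  proportionally to abundance times genome length, start positions are
  uniform, and per-base substitution errors are i.i.d.

Every read carries its genome of origin in a parseable read-id suffix
(``<id>|<genome>|<contig>|<start>|<strand>``), so truth labels survive a
round-trip through external FASTA/FASTQ/SAM files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MemberLookupError, ParameterError
from .genomes import GenomeRecord, codes_to_seq, reverse_complement, seq_to_codes

TRUTH_SEP = "|"


@dataclass
class CommunityDesign:
    """Composition and sequencing parameters of one synthetic metagenome.

    ``members`` maps genome ids to relative cell abundances (must sum to 1);
    read origins are drawn proportionally to abundance x genome length, i.e.
    abundances are organism abundances, not read fractions.
    """

    members: list[tuple[str, float]]
    n_reads: int
    read_length: int = 150
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ParameterError("n_reads must be positive")
        if self.read_length <= 0:
            raise ParameterError("read_length must be positive")
        if not (0 <= self.substitution_error_rate < 1):
            raise ParameterError("substitution_error_rate must be in [0, 1)")
        if not self.members:
            raise ParameterError("community has no members")
        abund = [a for _, a in self.members]
        if any(a <= 0 for a in abund):
            raise ParameterError("abundances must be positive")
        if abs(sum(abund) - 1.0) > 1e-6:
            raise ParameterError(f"abundances must sum to 1, got {sum(abund)}")


@dataclass
class Read:
    read_id: str
    sequence: str
    truth_genome_id: str | None = None
    truth_contig: int | None = None
    truth_start: int | None = None
    truth_strand: str | None = None


@dataclass
class ReadSet:
    reads: list[Read]
    read_length: int

    def __len__(self) -> int:
        return len(self.reads)


def make_truth_read_id(prefix: str, genome_id: str, contig: int, start: int, strand: str) -> str:
    return TRUTH_SEP.join([prefix, genome_id, str(contig), str(start), strand])


def parse_truth_read_id(read_id: str) -> tuple[str | None, int | None, int | None, str | None]:
    """Recover (genome_id, contig, start, strand) from a truth-labelled read id.

    Returns all-``None`` if the id does not carry the suffix.
    """
    parts = read_id.split(TRUTH_SEP)
    if len(parts) < 5:
        return None, None, None, None
    try:
        return parts[-4], int(parts[-3]), int(parts[-2]), parts[-1]
    except ValueError:
        return None, None, None, None


def expected_breadth(mean_depth: float) -> float:
    """Expected coverage breadth (%) under Poisson (Lander-Waterman) coverage.

    ``100 * (1 - exp(-depth))``: the probability that a position receives at
    least one read when per-position coverage is Poisson with the given mean.
    """
    if mean_depth < 0:
        raise ParameterError("mean_depth must be >= 0")
    return 100.0 * (1.0 - math.exp(-mean_depth))


def generate_genome(
    length_bp: int,
    gc: float,
    n_contigs: int = 1,
    seed: int = 0,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Draw an i.i.d. random genome at the requested G+C fraction.

    Bases are independent with P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2.
    Deterministic for a fixed seed.
    """
    if length_bp < 1000:
        raise ParameterError("length_bp must be >= 1000")
    if not (0 <= gc <= 1):
        raise ParameterError("gc must be in [0, 1]")
    if not (1 <= n_contigs <= length_bp // 500):
        raise ParameterError("n_contigs must be in [1, length_bp/500]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    codes = rng.choice(4, size=length_bp, p=p).astype(np.uint8)
    bounds = np.linspace(0, length_bp, n_contigs + 1).astype(int)
    contigs = [codes_to_seq(codes[bounds[i]: bounds[i + 1]]) for i in range(n_contigs)]
    gid = genome_id if genome_id is not None else f"g{seed}"
    return GenomeRecord(genome_id=gid, contigs=contigs)


def derive_relative(
    parent: GenomeRecord,
    substitution_rate: float,
    seed: int = 0,
    genome_id: str | None = None,
) -> GenomeRecord:
    """Create a relative by independent per-site substitution.

    Each site is replaced, with the given probability, by one of the three
    alternative bases chosen uniformly (no transition/transversion bias), so
    the expected nucleotide identity to the parent is ``100*(1-rate)`` %.
    Masked intervals are carried over unchanged.
    """
    if not (0 <= substitution_rate < 0.35):
        raise ParameterError("substitution_rate must be in [0, 0.35)")
    rng = np.random.default_rng(seed)
    contigs = []
    for seq in parent.contigs:
        codes = seq_to_codes(seq)
        hit = rng.random(codes.size) < substitution_rate
        offsets = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
        codes[hit] = (codes[hit] + offsets) % 4
        contigs.append(codes_to_seq(codes))
    gid = genome_id if genome_id is not None else f"{parent.genome_id}_rel"
    return GenomeRecord(
        genome_id=gid,
        contigs=contigs,
        masked_intervals=list(parent.masked_intervals),
    )


def plant_shared_repeat(
    genomes: list[GenomeRecord],
    repeat_length: int = 5000,
    copies_per_genome: int = 1,
    seed: int = 0,
    gc: float = 0.5,
) -> list[GenomeRecord]:
    """Insert one shared repeat sequence into every genome.

    The same repeat (an rRNA-operon analogue: near-identical across species)
    is inserted at random positions; every insertion is recorded in the
    genome's masked intervals so coverage computations can exclude it.
    Returns new records; inputs are not modified.
    """
    if repeat_length < 100:
        raise ParameterError("repeat_length must be >= 100")
    if not genomes:
        raise ParameterError("genomes must be non-empty")
    if copies_per_genome < 0:
        raise ParameterError("copies_per_genome must be >= 0")
    if copies_per_genome == 0:
        return [
            GenomeRecord(g.genome_id, list(g.contigs), list(g.masked_intervals))
            for g in genomes
        ]
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    repeat = codes_to_seq(rng.choice(4, size=repeat_length, p=p).astype(np.uint8))

    out = []
    for g in genomes:
        if min(len(c) for c in g.contigs) < repeat_length:
            raise ParameterError(
                f"repeat ({repeat_length} bp) longer than the shortest contig of {g.genome_id!r}"
            )
        contigs = list(g.contigs)
        intervals = list(g.masked_intervals)
        for _ in range(copies_per_genome):
            ci = int(rng.integers(len(contigs)))
            pos = int(rng.integers(len(contigs[ci]) + 1))
            contigs[ci] = contigs[ci][:pos] + repeat + contigs[ci][pos:]
            shifted = []
            for c, s, e in intervals:
                if c == ci and s >= pos:
                    shifted.append((c, s + repeat_length, e + repeat_length))
                elif c == ci and s < pos < e:
                    # insertion splits an existing masked interval
                    shifted.append((c, s, pos))
                    shifted.append((c, pos + repeat_length, e + repeat_length))
                else:
                    shifted.append((c, s, e))
            shifted.append((ci, pos, pos + repeat_length))
            intervals = shifted
        out.append(GenomeRecord(g.genome_id, contigs, intervals))
    return out


def simulate_metagenome(design: CommunityDesign, genomes: list[GenomeRecord]) -> ReadSet:
    """Draw labelled shotgun reads from a community of genomes.

    Read counts per genome are multinomial with probabilities proportional to
    abundance x genome length; start positions are uniform over valid
    (full-read-length) starts; each read is taken from either strand with
    probability 1/2; substitution errors are i.i.d. per base.  Deterministic
    for a fixed ``design.seed``.
    """
    by_id = {g.genome_id: g for g in genomes}
    for gid, _ in design.members:
        if gid not in by_id:
            raise MemberLookupError(f"community member {gid!r} not among supplied genomes")
    rng = np.random.default_rng(design.seed)
    L = design.read_length

    member_genomes = [by_id[gid] for gid, _ in design.members]
    weights = np.array([a * g.total_length for (_, a), g in zip(design.members, member_genomes)])
    counts = rng.multinomial(design.n_reads, weights / weights.sum())

    reads: list[Read] = []
    serial = 0
    for (gid, _), g, n in zip(design.members, member_genomes, counts):
        codes = g.contig_codes()
        valid = np.array([max(0, c.size - L + 1) for c in codes], dtype=float)
        if valid.sum() == 0:
            raise ParameterError(
                f"no contig of {gid!r} can host a {L} bp read"
            )
        contig_choice = rng.choice(len(codes), size=n, p=valid / valid.sum())
        for ci in contig_choice:
            start = int(rng.integers(int(valid[ci])))
            frag = codes[ci][start: start + L].copy()
            if design.substitution_error_rate > 0:
                hit = rng.random(L) < design.substitution_error_rate
                offs = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
                frag[hit] = (frag[hit] + offs) % 4
            seq = codes_to_seq(frag)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                seq = reverse_complement(seq)
            rid = make_truth_read_id(f"r{serial}", gid, int(ci), start, strand)
            reads.append(Read(rid, seq, gid, int(ci), start, strand))
            serial += 1
    return ReadSet(reads=reads, read_length=L)
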