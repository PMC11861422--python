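"""Genome-based species demarcation: ANI, digital DDH, 16S identity.

Two strains belong to the same prokaryotic species when their whole-genome
average nucleotide identity (ANI) is >= 95% AND their digital DNA-DNA
hybridization (dDDH) estimate is >= 70%; 16S rRNA identity (conventional
weak threshold 98.7%) is reported but never sufficient on its own, because
closely related freshwater species routinely share 99.3-100% 16S identity.

ANI here is fragment-based (ANIb convention): the query is cut into
consecutive 1020 bp fragments, each is placed on the subject by exact k-mer
seeding and ungapped extension, fragments are kept at >= 70% identity over
>= 70% coverage, and the ANI is the mean identity of kept fragments,
averaged over both directions.

dDDH uses the GBDP-style ``d4`` distance: 1 minus the fraction of identical
bases within high-scoring segment pairs, mapped to a DDH percentage through
a logistic transform (see :data:`DDH_LOGISTIC`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .errors import DataError, ParameterError
from .genomes import GenomeRecord, seq_to_codes

#: Logistic transform ``ddh% = 100 / (1 + exp(intercept + slope * d4))``.
#: Calibrated so the d4 distance of 0.05 — the divergence at the 95% ANI
#: species boundary — maps to exactly 70% dDDH, and d4 = 0 maps to ~99.3%.
DDH_LOGISTIC = {"intercept": -5.0, "slope": (math.log(3.0 / 7.0) + 5.0) / 0.05}


@dataclass
class ANIResult:
    genome_a: str
    genome_b: str
    ani_pct: float
    aligned_fraction: float
    fragments_total: int
    fragments_used: int
    flagged: bool = False  # True when no fragment survived the filters


@dataclass
class DDHResult:
    genome_a: str
    genome_b: str
    d4_distance: float
    ddh_pct: float
    flagged: bool = False  # True when no HSP was found


@dataclass
class SpeciesDecision:
    genome_a: str
    genome_b: str
    ani_pct: float
    ddh_pct: float
    s16_identity_pct: float | None
    same_species: bool
    evidence: list[tuple[str, float, float, str]] = field(default_factory=list)


def _genome_codes(g: GenomeRecord) -> np.ndarray:
    return np.concatenate([seq_to_codes(c) for c in g.contigs])


class _KmerIndex:
    """Exact k-mer positions over a concatenated genome (forward strand)."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        self.n = codes.size
        raw = codes.tobytes()
        self.index: dict[bytes, list[int]] = {}
        for pos in range(0, self.n - k + 1):
            self.index.setdefault(raw[pos: pos + k], []).append(pos)

    def lookup(self, kmer: bytes) -> list[int]:
        return self.index.get(kmer, [])


def _best_diagonal(
    frag: np.ndarray,
    subject: np.ndarray,
    idx: _KmerIndex,
    max_diagonals: int = 8,
) -> tuple[int, float] | None:
    """Best ungapped placement of a fragment on the subject.

    Seeds at every (k+1)-spaced offset; each distinct implied diagonal is
    scored by full ungapped comparison.  Returns (matches, coverage) of the
    best diagonal, or None when no seed hits.
    """
    k = idx.k
    L = frag.size
    raw = frag.tobytes()
    diagonals: list[int] = []
    seen: set[int] = set()
    for off in range(0, L - k + 1, k + 1):
        for pos in idx.lookup(raw[off: off + k]):
            d0 = pos - off
            if d0 not in seen:
                seen.add(d0)
                diagonals.append(d0)
        if len(diagonals) >= max_diagonals:
            break
    if not diagonals:
        return None
    best = None
    for d0 in diagonals:
        s = max(d0, 0)
        e = min(d0 + L, idx.n)
        if e <= s:
            continue
        overlap = subject[s:e]
        q = frag[s - d0: e - d0]
        matches = int((q == overlap).sum())
        cov = (e - s) / L
        ident = matches / (e - s)
        if best is None or (ident, cov) > (best[0], best[1]):
            best = (ident, cov, matches)
    if best is None:
        return None
    return best[2], best[1]


def _oneway_fragment_stats(
    query: GenomeRecord,
    subject_codes: np.ndarray,
    idx: _KmerIndex,
    fragment_bp: int,
    min_identity_pct: float,
    min_cov: float,
    collect_all_hsps: bool = False,
    min_hsp_identity_pct: float = 50.0,
):
    """Cut the query into fragments and place each on the subject.

    Returns (kept identities, total fragments, kept count, kept matches,
    kept aligned length) under the ANI filters, plus HSP sums under the
    looser HSP filter when ``collect_all_hsps``.
    """
    identities: list[float] = []
    total = kept = 0
    hsp_matches = hsp_len = 0
    for seq in query.contigs:
        codes = seq_to_codes(seq)
        for s in range(0, codes.size - fragment_bp + 1, fragment_bp):
            frag = codes[s: s + fragment_bp]
            total += 1
            hit = _best_diagonal(frag, subject_codes, idx)
            if hit is None:
                continue
            matches, cov = hit
            ident = 100.0 * matches / (cov * fragment_bp)
            if collect_all_hsps and ident >= min_hsp_identity_pct and cov >= min_cov:
                hsp_matches += matches
                hsp_len += int(round(cov * fragment_bp))
            if ident >= min_identity_pct and cov >= min_cov:
                kept += 1
                identities.append(ident)
    return identities, total, kept, hsp_matches, hsp_len


def fragment_ani(
    a: GenomeRecord,
    b: GenomeRecord,
    fragment_bp: int = 1020,
    min_fragment_identity_pct: float = 70.0,
    min_fragment_cov: float = 0.7,
    k: int = 15,
) -> ANIResult:
    """Symmetric fragment-based average nucleotide identity (ANIb-style).

    Both genomes must be at least 10 fragments long.  When no fragment
    survives the filters in either direction (unrelated genomes), the result
    is flagged and ``ani_pct`` is reported as 0.
    """
    for g in (a, b):
        if g.total_length < 10 * fragment_bp:
            raise ParameterError(
                f"genome {g.genome_id!r} shorter than 10 fragments ({10 * fragment_bp} bp)"
            )
    codes_a, codes_b = _genome_codes(a), _genome_codes(b)
    idx_a, idx_b = _KmerIndex(codes_a, k), _KmerIndex(codes_b, k)

    id_ab, tot_ab, kept_ab, _, _ = _oneway_fragment_stats(
        a, codes_b, idx_b, fragment_bp, min_fragment_identity_pct, min_fragment_cov
    )
    id_ba, tot_ba, kept_ba, _, _ = _oneway_fragment_stats(
        b, codes_a, idx_a, fragment_bp, min_fragment_identity_pct, min_fragment_cov
    )
    total = tot_ab + tot_ba
    used = kept_ab + kept_ba
    if used == 0:
        warnings.warn(
            f"no fragment of {a.genome_id!r}/{b.genome_id!r} passed the ANI filters; "
            "genomes are likely unrelated",
            stacklevel=2,
        )
        return ANIResult(a.genome_id, b.genome_id, 0.0, 0.0, total, 0, flagged=True)
    ani = float(np.mean(id_ab + id_ba))
    aligned_fraction = used / total
    return ANIResult(a.genome_id, b.genome_id, ani, aligned_fraction, total, used)


def gbdp_d4(
    a: GenomeRecord,
    b: GenomeRecord,
    window_bp: int = 1020,
    min_hsp_identity_pct: float = 50.0,
    min_hsp_cov: float = 0.7,
    k: int = 15,
) -> DDHResult:
    """GBDP-style d4 distance and its digital-DDH transform.

    High-scoring segment pairs are seeded windows placed by ungapped
    extension; ``d4 = 1 - (summed identities across HSPs / total HSP
    length)``, averaged over both directions, then mapped to a DDH
    percentage through :data:`DDH_LOGISTIC`.
    """
    codes_a, codes_b = _genome_codes(a), _genome_codes(b)
    idx_a, idx_b = _KmerIndex(codes_a, k), _KmerIndex(codes_b, k)
    sums = []
    for query, subject, idx in ((a, codes_b, idx_b), (b, codes_a, idx_a)):
        _, _, _, m, ln = _oneway_fragment_stats(
            query, subject, idx, window_bp,
            min_identity_pct=101.0,  # ANI filter disabled; HSP sums only
            min_cov=min_hsp_cov,
            collect_all_hsps=True,
            min_hsp_identity_pct=min_hsp_identity_pct,
        )
        sums.append((m, ln))
    total_len = sum(ln for _, ln in sums)
    if total_len == 0:
        warnings.warn(
            f"no HSP between {a.genome_id!r} and {b.genome_id!r}; dDDH reported as 0",
            stacklevel=2,
        )
        return DDHResult(a.genome_id, b.genome_id, d4_distance=1.0, ddh_pct=0.0, flagged=True)
    total_matches = sum(m for m, _ in sums)
    d4 = 1.0 - total_matches / total_len
    return DDHResult(a.genome_id, b.genome_id, d4_distance=d4, ddh_pct=ddh_from_d4(d4))


def ddh_from_d4(d4: float) -> float:
    """Map a d4 distance to a DDH percentage (monotone decreasing logistic)."""
    if d4 < 0:
        raise ParameterError("d4 must be >= 0")
    return 100.0 / (1.0 + math.exp(DDH_LOGISTIC["intercept"] + DDH_LOGISTIC["slope"] * d4))


_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=2,
    mismatch_score=-1,
    open_gap_score=-4,
    extend_gap_score=-1,
)


def pairwise_16s_identity(seq_a: str, seq_b: str, min_length: int = 500) -> float:
    """Global-alignment identity (%) of two marker-gene sequences.

    Terminal-gap columns are trimmed before counting (a shorter exact
    substring therefore scores 100%); internal gap columns count against
    identity.
    """
    if len(seq_a) < min_length or len(seq_b) < min_length:
        raise ParameterError(f"sequences must be >= {min_length} bp")
    aln = _ALIGNER.align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    if end <= start:
        raise DataError("alignment has no overlapping columns after trimming")
    cols = end - start
    matches = sum(1 for x, y in zip(row_a[start:end], row_b[start:end]) if x == y and x != "-")
    return 100.0 * matches / cols


ANI_SPECIES_THRESHOLD = 95.0
DDH_SPECIES_THRESHOLD = 70.0
S16_SPECIES_THRESHOLD = 98.7


def species_demarcation(
    ani: ANIResult,
    ddh: DDHResult,
    s16_pct: float | None = None,
) -> SpeciesDecision:
    """Apply the conjunctive species rule: same species iff ANI >= 95 and dDDH >= 70.

    16S identity above 98.7% is recorded as inconclusive — it cannot by
    itself demonstrate conspecificity, since distinct species in this group
    share near-identical 16S genes.
    """
    if {ani.genome_a, ani.genome_b} != {ddh.genome_a, ddh.genome_b}:
        raise ParameterError(
            f"ANI pair ({ani.genome_a}, {ani.genome_b}) does not match "
            f"dDDH pair ({ddh.genome_a}, {ddh.genome_b})"
        )
    ani_ok = ani.ani_pct >= ANI_SPECIES_THRESHOLD
    ddh_ok = ddh.ddh_pct >= DDH_SPECIES_THRESHOLD
    evidence = [
        ("ANI", ANI_SPECIES_THRESHOLD, ani.ani_pct, "pass" if ani_ok else "fail"),
        ("dDDH", DDH_SPECIES_THRESHOLD, ddh.ddh_pct, "pass" if ddh_ok else "fail"),
    ]
    if s16_pct is not None:
        verdict = (
            "inconclusive — genome indices required"
            if s16_pct >= S16_SPECIES_THRESHOLD
            else "below"
        )
        evidence.append(("16S", S16_SPECIES_THRESHOLD, s16_pct, verdict))
    return SpeciesDecision(
        genome_a=ani.genome_a,
        genome_b=ani.genome_b,
        ani_pct=ani.ani_pct,
        ddh_pct=ddh.ddh_pct,
        s16_identity_pct=s16_pct,
        same_species=ani_ok and ddh_ok,
        evidence=evidence,
    )
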