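"""Core-gene selection from pan-genomes and concatenated alignments.

Protein sequences from a set of genomes are clustered greedily against
family centroids at a global-identity threshold (default 70%); a family is
*core* when every genome contributes at least one member.  One
representative per genome per core family is aligned with a simple
center-star progressive aligner and the family alignments are concatenated
in stable family order — the input expected by downstream tree building.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ParameterError
from .phylo import MultipleAlignment

logger = logging.getLogger(__name__)

_PROT_ALIGNER = Align.PairwiseAligner(
    mode="global",
    substitution_matrix=substitution_matrices.load("BLOSUM62"),
    open_gap_score=-11,
    extend_gap_score=-1,
)


def _trimmed_identity(row_a: str, row_b: str) -> float:
    """Identity (%) over aligned columns, terminal-gap columns excluded."""
    start, end = 0, len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    matches = sum(1 for x, y in zip(row_a[start:end], row_b[start:end]) if x == y and x != "-")
    return 100.0 * matches / (end - start)


def protein_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity (%) of two protein sequences."""
    aln = _PROT_ALIGNER.align(seq_a, seq_b)[0]
    return _trimmed_identity(str(aln[0]), str(aln[1]))


@dataclass
class GeneFamily:
    family_id: str
    centroid: str  # centroid protein sequence
    members: dict[str, list[tuple[str, str]]]  # genome -> [(gene_id, seq)]
    is_core: bool = False


@dataclass
class GeneFamilyTable:
    genomes: list[str]
    families: list[GeneFamily] = field(default_factory=list)

    def core_families(self) -> list[GeneFamily]:
        return [f for f in self.families if f.is_core]


def _center_star_align(seqs: list[str]) -> list[str]:
    """Center-star multiple alignment: all members aligned to the longest.

    Pairwise alignments to the center are merged by padding insertions
    relative to center coordinates.  Adequate for families of homologous
    proteins; not a general-purpose MSA.
    """
    if len(seqs) == 1:
        return list(seqs)
    center_i = max(range(len(seqs)), key=lambda i: len(seqs[i]))
    center = seqs[center_i]
    pairs: list[tuple[str, str]] = []  # (gapped center, gapped member)
    for i, s in enumerate(seqs):
        if i == center_i:
            pairs.append((center, center))
        else:
            a = _PROT_ALIGNER.align(center, s)[0]
            pairs.append((str(a[0]), str(a[1])))

    # insertion length needed after each center position (0..len(center))
    ins = [0] * (len(center) + 1)
    parsed = []
    for gc, gm in pairs:
        segs: list[tuple[str, str]] = []  # per center slot: (insertion, aligned char)
        cpos = 0
        pending = ""
        cols = []
        for x, y in zip(gc, gm):
            if x == "-":
                pending += y
            else:
                cols.append((pending, y))
                pending = ""
                cpos += 1
        parsed.append((cols, pending))
        for p, (pre, _) in enumerate(cols):
            ins[p] = max(ins[p], len(pre))
        ins[len(center)] = max(ins[len(center)], len(pending))

    rows = []
    for cols, tail in parsed:
        out = []
        for p, (pre, ch) in enumerate(cols):
            out.append(pre.rjust(ins[p], "-"))
            out.append(ch)
        out.append(tail.ljust(ins[len(center)], "-"))
        rows.append("".join(out))
    return rows


def core_gene_selection(
    gene_sets: dict[str, list[tuple[str, str]]],
    min_identity_pct: float = 70.0,
) -> tuple[GeneFamilyTable, MultipleAlignment | None]:
    """Cluster proteins into families and concatenate core-family alignments.

    ``gene_sets`` maps genome id to (gene_id, protein sequence) pairs.
    Genes are clustered greedily: each gene (longest first) joins the
    best-matching existing centroid at >= ``min_identity_pct`` global
    identity, else founds a new family.  Families present in 100% of
    genomes are core; one representative per genome (first encountered) per
    core family is aligned and the alignments concatenated in family order.
    Returns ``(table, None)`` with a warning when no family is core.
    """
    if len(gene_sets) < 2:
        raise ParameterError("need at least 2 genomes")
    for gid, genes in gene_sets.items():
        if not genes:
            raise ParameterError(f"genome {gid!r} has no genes")

    genomes = list(gene_sets)
    entries = [
        (genome, gene_id, seq)
        for genome in genomes
        for gene_id, seq in gene_sets[genome]
    ]
    entries.sort(key=lambda e: (-len(e[2]), e[0], e[1]))

    families: list[GeneFamily] = []
    for genome, gene_id, seq in entries:
        best = None
        for fam in families:
            ratio = min(len(seq), len(fam.centroid)) / max(len(seq), len(fam.centroid))
            if 100.0 * ratio < min_identity_pct:
                continue  # even a perfect overlap could not reach the threshold
            ident = protein_identity(fam.centroid, seq)
            if ident >= min_identity_pct and (best is None or ident > best[0]):
                best = (ident, fam)
        if best is None:
            families.append(
                GeneFamily(
                    family_id=f"fam{len(families):05d}",
                    centroid=seq,
                    members={genome: [(gene_id, seq)]},
                )
            )
        else:
            best[1].members.setdefault(genome, []).append((gene_id, seq))

    for fam in families:
        fam.is_core = all(genome in fam.members for genome in genomes)
    table = GeneFamilyTable(genomes=genomes, families=families)

    core = table.core_families()
    if not core:
        logger.warning("no core gene families at %.0f%% identity", min_identity_pct)
        return table, None

    concat_rows = {g: [] for g in genomes}
    for fam in sorted(core, key=lambda f: f.family_id):
        reps = [fam.members[g][0][1] for g in genomes]
        aligned = _center_star_align(reps)
        width = len(aligned[0])
        assert all(len(r) == width for r in aligned)
        for g, row in zip(genomes, aligned):
            concat_rows[g].append(row)
    aln = MultipleAlignment(
        taxa=list(genomes),
        rows=["".join(concat_rows[g]) for g in genomes],
    )
    return table, aln
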