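"""Distance-based phylogenetics: K2P distances, neighbour joining, bootstrap.

Configured the way 16S marker trees are usually built for closely related
freshwater taxa: Kimura 2-parameter distances (optionally gamma-corrected)
with pairwise deletion of gaps and ambiguous sites, Saitou-Nei neighbour
joining, nonparametric bootstrap over alignment columns, and midpoint
rooting.  Trees are :class:`skbio.TreeNode` objects and serialize to Newick
with bootstrap supports as internal-node labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode

from .errors import DataError, ParameterError, RootingError, SaturationError

logger = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


@dataclass
class MultipleAlignment:
    """Equal-length aligned rows (nucleotide or protein) with unique taxa."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise DataError("taxa and rows differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise DataError("taxa must be unique")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise DataError("all alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def subset_columns(self, cols: np.ndarray) -> "MultipleAlignment":
        arr = np.array([list(r) for r in self.rows])
        sub = arr[:, cols]
        return MultipleAlignment(list(self.taxa), ["".join(r) for r in sub])


def _pq_counts(row_a: str, row_b: str) -> tuple[int, int, int]:
    """(comparable sites, transitions, transversions) under pairwise deletion.

    Sites where either row is not an unambiguous A/C/G/T (gaps, N, ambiguity
    codes) are excluded from all counts.
    """
    a = np.frombuffer(row_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.upper().encode(), dtype=np.uint8)
    if a.size != b.size:
        raise DataError("aligned rows differ in length")
    code = np.full(256, 255, dtype=np.uint8)
    for i, base in enumerate(b"AGCT"):  # purines 0,1; pyrimidines 2,3
        code[base] = i
    ca, cb = code[a], code[b]
    ok = (ca != 255) & (cb != 255)
    ca, cb = ca[ok], cb[ok]
    diff = ca != cb
    same_class = (ca // 2) == (cb // 2)
    transitions = int((diff & same_class).sum())
    transversions = int((diff & ~same_class).sum())
    return int(ok.sum()), transitions, transversions


def k2p_distance(
    row_a: str,
    row_b: str,
    gamma_shape: float | None = None,
    min_sites: int = 50,
) -> float:
    """Kimura 2-parameter distance between two aligned rows.

    ``d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q)`` with P/Q the transition and
    transversion proportions over comparable sites; with a gamma shape ``a``
    the rate-heterogeneity-corrected form
    ``d = a/2 [(1-2P-Q)^(-1/a) - 1] + a/4 [(1-2Q)^(-1/a) - 1]`` is used.
    """
    n, ts, tv = _pq_counts(row_a, row_b)
    if n < min_sites:
        raise DataError(f"only {n} comparable sites after pairwise deletion (need >= {min_sites})")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P distance undefined (saturated): P={P:.4f}, Q={Q:.4f}"
        )
    if gamma_shape is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    if gamma_shape <= 0:
        raise ParameterError("gamma_shape must be positive")
    a = gamma_shape
    return (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (w2 ** (-1.0 / a) - 1.0)


def distance_matrix(
    aln: MultipleAlignment,
    gamma_shape: float | None = None,
    min_sites: int = 50,
) -> DistanceMatrix:
    """All-pairs K2P distances; symmetric with zero diagonal."""
    n = len(aln.taxa)
    if n < 3:
        raise ParameterError("need at least 3 taxa")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = k2p_distance(aln.rows[i], aln.rows[j], gamma_shape, min_sites)
            except SaturationError as exc:
                raise SaturationError(
                    f"pair ({aln.taxa[i]}, {aln.taxa[j]}): {exc}"
                ) from exc
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=aln.taxa)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; returns an unrooted (trifurcating) tree.

    The Q criterion is minimized with ties broken by the lowest pair of node
    creation indices; negative intermediate branch lengths are clamped to 0
    with the remainder shifted to the sibling edge.
    """
    n = dm.shape[0]
    if n < 3:
        raise ParameterError("neighbour joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.data)):
        raise DataError("distance matrix contains non-finite entries")

    nodes: dict[int, TreeNode] = {i: TreeNode(name=t) for i, t in enumerate(dm.ids)}
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dm.data[i, j])

    def get(i: int, j: int) -> float:
        return D[(i, j) if i < j else (j, i)]

    active = list(range(n))
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = get(i, j)
        di = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        dj = dij - di
        if di < 0:
            dj, di = dij, 0.0
        elif dj < 0:
            di, dj = dij, 0.0
        u = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = di, dj
        nodes[next_id] = u
        for kk in active:
            if kk in (i, j):
                continue
            duk = 0.5 * (get(i, kk) + get(j, kk) - dij)
            D[(min(kk, next_id), max(kk, next_id))] = max(duk, 0.0)
        active = [x for x in active if x not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    dij, dik, djk = get(i, j), get(i, k), get(j, k)
    li = max(0.5 * (dij + dik - djk), 0.0)
    lj = max(0.5 * (dij + djk - dik), 0.0)
    lk = max(0.5 * (dik + djk - dij), 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    nodes[i].length, nodes[j].length, nodes[k].length = li, lj, lk
    return root


def _bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Internal bipartitions as canonical frozensets of tip names.

    Each internal edge splits the tips in two; the canonical form is the
    lexicographically smaller of the two sides at equal size, else the
    smaller side.  Trivial splits (single tip / all tips) are excluded.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        key = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        out[key] = node
    return out


def bootstrap_support(
    aln: MultipleAlignment,
    n_replicates: int = 1000,
    gamma_shape: float | None = None,
    seed: int = 0,
    min_sites: int = 50,
) -> TreeNode:
    """NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate; support is the
    percentage of successful replicates whose NJ tree contains each internal
    bipartition of the full-data tree.  Replicates whose distance matrix
    saturates are dropped and counted (warning above 5% dropped).
    """
    full = nj_tree(distance_matrix(aln, gamma_shape, min_sites))
    biparts = _bipartitions(full)
    counts = {key: 0 for key in biparts}
    rng = np.random.default_rng(seed)
    dropped = 0
    for _ in range(n_replicates):
        cols = rng.integers(aln.length, size=aln.length)
        try:
            rep = nj_tree(distance_matrix(aln.subset_columns(cols), gamma_shape, min_sites))
        except (SaturationError, DataError):
            dropped += 1
            continue
        rep_biparts = _bipartitions(rep)
        for key in counts:
            if key in rep_biparts:
                counts[key] += 1
    used = n_replicates - dropped
    if dropped > 0.05 * n_replicates:
        logger.warning("%d/%d bootstrap replicates dropped (saturation)", dropped, n_replicates)
    if used == 0:
        raise DataError("all bootstrap replicates failed")
    for key, node in biparts.items():
        support = 100.0 * counts[key] / used
        node.support_pct = support
        node.name = f"{support:.0f}"
    return full


@dataclass
class BlockFilterResult:
    alignment: MultipleAlignment
    kept_columns: np.ndarray  # original column indices that survived
    n_blocks: int


def conserved_block_filter(
    aln: MultipleAlignment,
    max_gap_fraction: float = 0.5,
    min_block_length: int = 10,
) -> BlockFilterResult:
    """Drop gappy columns and short conserved islands (Gblocks-style, simplified).

    Columns whose gap fraction exceeds ``max_gap_fraction`` are removed;
    surviving runs of consecutive columns shorter than ``min_block_length``
    are removed too.  An empty result is returned with a warning rather than
    an error.
    """
    if not (0 <= max_gap_fraction <= 1):
        raise ParameterError("max_gap_fraction must be in [0, 1]")
    if min_block_length < 1:
        raise ParameterError("min_block_length must be >= 1")
    arr = np.array([list(r) for r in aln.rows])
    gap_frac = (arr == "-").mean(axis=0)
    keep = gap_frac <= max_gap_fraction

    kept_cols: list[int] = []
    n_blocks = 0
    run: list[int] = []
    for col in range(aln.length + 1):
        if col < aln.length and keep[col]:
            run.append(col)
        else:
            if len(run) >= min_block_length:
                kept_cols.extend(run)
                n_blocks += 1
            run = []
    cols = np.array(kept_cols, dtype=int)
    if cols.size == 0:
        logger.warning("conserved-block filter removed every column")
        return BlockFilterResult(MultipleAlignment(list(aln.taxa), [""] * len(aln.taxa)), cols, 0)
    return BlockFilterResult(aln.subset_columns(cols), cols, n_blocks)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest tip-to-tip path.

    Ties between equally long paths are broken by the lexicographically
    smallest tip-name pair.  All pairwise tip path lengths are preserved.
    """
    tips = sorted(tree.tips(), key=lambda t: t.name)
    if len(tips) < 2:
        raise RootingError("midpoint rooting needs at least 2 tips")
    dmat = tree.tip_tip_distances()
    best = None
    for i in range(len(tips)):
        for j in range(i + 1, len(tips)):
            d = float(dmat[tips[i].name, tips[j].name])
            if best is None or d > best[0] + 1e-12:
                best = (d, tips[i].name, tips[j].name)
    diameter, name_a, name_b = best
    if diameter <= 0:
        raise RootingError("all path lengths are zero; cannot midpoint-root")
    half = diameter / 2.0

    node_a = tree.find(name_a)
    node_b = tree.find(name_b)
    lca = tree.lowest_common_ancestor([node_a, node_b])

    def walk(start: TreeNode):
        """Yield (node, cumulative length from start up to and including node's edge)."""
        cum = 0.0
        node = start
        while node is not lca:
            cum += node.length or 0.0
            yield node, cum
            node = node.parent

    target, remainder = None, None
    for node, cum in walk(node_a):
        if cum >= half - 1e-12:
            target = node
            remainder = (node.length or 0.0) - (cum - half)
            break
    if target is None:
        d_from_b = diameter - half
        for node, cum in walk(node_b):
            if cum >= d_from_b - 1e-12:
                target = node
                remainder = (node.length or 0.0) - (cum - d_from_b)
                break
    if target is None:  # pragma: no cover - numeric corner
        raise RootingError("failed to locate the midpoint edge")
    remainder = min(max(remainder, 0.0), target.length or 0.0)
    return tree.root_at(target, above=remainder)
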