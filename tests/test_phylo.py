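"""K2P distances, neighbour joining, bootstrap, rooting, block filter."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import TreeNode
from skbio.tree import nj as skbio_nj

from aquadetect import (
    DataError,
    MultipleAlignment,
    ParameterError,
    RootingError,
    SaturationError,
    bootstrap_support,
    conserved_block_filter,
    distance_matrix,
    k2p_distance,
    midpoint_root,
    nj_tree,
)


def _seq_with_counts(n, transitions, transversions):
    """Row pair with exact substitution counts (counting oracle input)."""
    a = "A" * n
    b = "G" * transitions + "C" * transversions + "A" * (n - transitions - transversions)
    return a, b


def _random_additive(rng, n_taxa):
    """Random binary tree -> (taxa, additive distance matrix, tree)."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.05, 1.0))
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(children=[nodes[i], nodes[j]])
        parent.length = float(rng.uniform(0.05, 1.0))
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(children=nodes)
    ids = sorted(t.name for t in root.tips())
    dm = root.tip_tip_distances().filter(ids)
    return DistanceMatrix(dm.data, ids=ids), root


class TestK2P:
    def test_identical_rows(self):
        assert k2p_distance("ACGT" * 30, "ACGT" * 30) == 0.0

    def test_transitions_only_closed_form(self):
        a, b = _seq_with_counts(100, 10, 0)
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8), rel=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_counting_oracle(self, seed):
        # build rows with known (P, Q), compare against the closed form
        rng = np.random.default_rng(seed)
        n = 400
        ts = int(rng.integers(5, 40))
        tv = int(rng.integers(5, 40))
        a, b = _seq_with_counts(n, ts, tv)
        P, Q = ts / n, tv / n
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert k2p_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_gamma_form_and_limit(self):
        a, b = _seq_with_counts(200, 20, 10)
        P, Q = 0.1, 0.05
        shape = 0.5
        expected = (shape / 2) * ((1 - 2 * P - Q) ** (-1 / shape) - 1) + (shape / 4) * (
            (1 - 2 * Q) ** (-1 / shape) - 1
        )
        assert k2p_distance(a, b, gamma_shape=shape) == pytest.approx(expected, rel=1e-12)
        # large shape approaches the uncorrected distance
        assert k2p_distance(a, b, gamma_shape=1e7) == pytest.approx(
            k2p_distance(a, b), rel=1e-5
        )

    def test_pairwise_deletion(self):
        # gap and N columns drop out of both numerator and denominator
        a = "A" * 100 + "-N"
        b = "G" * 10 + "A" * 90 + "CC"
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.8), rel=1e-12)

    def test_saturation_error(self):
        a, b = _seq_with_counts(100, 50, 10)
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_too_few_sites(self):
        with pytest.raises(DataError):
            k2p_distance("ACGT" * 5, "ACGT" * 5)


class TestDistanceMatrix:
    def test_identical_rows_zero_matrix(self):
        aln = MultipleAlignment(["a", "b", "c"], ["ACGT" * 30] * 3)
        dm = distance_matrix(aln)
        assert np.allclose(dm.data, 0.0)

    def test_elementwise_oracle_and_symmetry(self):
        rng = np.random.default_rng(3)
        rows = ["".join("ACGT"[i] for i in rng.integers(0, 4, 300)) for _ in range(4)]
        aln = MultipleAlignment(list("wxyz"), rows)
        # random rows are near saturation for K2P; mutate from one base row instead
        base = rows[0]
        derived = []
        for k in range(4):
            s = list(base)
            for p in rng.choice(300, size=10 * (k + 1), replace=False):
                s[p] = "ACGT"[(("ACGT".index(s[p])) + 1) % 4]
            derived.append("".join(s))
        aln = MultipleAlignment(list("wxyz"), derived)
        dm = distance_matrix(aln)
        for i in range(4):
            for j in range(4):
                expected = 0.0 if i == j else k2p_distance(derived[i], derived[j])
                assert dm.data[i, j] == pytest.approx(expected, rel=1e-12)
        assert np.allclose(dm.data, dm.data.T)

    def test_saturation_names_pair(self):
        good = "ACGT" * 30
        bad = "GTAC" * 30  # every site differs
        aln = MultipleAlignment(["a", "b", "c"], [good, good, bad])
        with pytest.raises(SaturationError, match="c"):
            distance_matrix(aln)


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), ids=list("abc"))
        t = nj_tree(dm)
        lengths = {tip.name: tip.length for tip in t.tips()}
        # three-point formulas: la=(3+4-5)/2=1, lb=(3+5-4)/2=2, lc=(4+5-3)/2=3
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}
        assert len(t.children) == 3

    def test_additive_recovery_exact(self):
        rng = np.random.default_rng(0)
        dm, source = _random_additive(rng, 6)
        t = nj_tree(dm)
        rec = t.tip_tip_distances().filter(dm.ids)
        assert np.allclose(rec.data, dm.data, atol=1e-9)
        assert t.compare_rfd(source) == 0.0

    def test_matches_skbio_on_additive(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            dm, _source = _random_additive(rng, 8)
            assert nj_tree(dm).compare_rfd(skbio_nj(dm)) == 0.0

    def test_ultrametric_matches_upgma_topology(self):
        # perfectly ultrametric distances: NJ and average-linkage agree
        from scipy.cluster.hierarchy import average, to_tree

        dm = DistanceMatrix(
            np.array(
                [
                    [0, 2, 8, 8],
                    [2, 0, 8, 8],
                    [8, 8, 0, 4],
                    [8, 8, 4, 0],
                ],
                float,
            ),
            ids=list("abcd"),
        )
        t = nj_tree(dm)
        # expected split {a,b} | {c,d}
        sides = [frozenset(x.name for x in ch.tips()) or frozenset({ch.name})
                 for ch in t.children]
        assert frozenset("ab") in sides or frozenset("cd") in sides

    def test_nonfinite_rejected(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = np.inf
        with pytest.raises(DataError):
            nj_tree(DistanceMatrix(m, ids=list("abc")))


def _clade_alignment(seed=0, n_cols=600, clade_rate=0.12, tip_rate=0.02):
    """Two clearly separated 3-tip clades."""
    rng = np.random.default_rng(seed)

    def mut(s, rate):
        out = list(s)
        for i in range(len(out)):
            if rng.random() < rate:
                out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
        return "".join(out)

    base = "".join("ACGT"[i] for i in rng.integers(0, 4, n_cols))
    clade = mut(base, clade_rate)
    rows = [mut(clade, tip_rate) for _ in range(3)] + [mut(base, tip_rate) for _ in range(3)]
    return MultipleAlignment([f"t{i}" for i in range(6)], rows)


class TestBootstrap:
    def test_clear_clades_high_support(self):
        aln = _clade_alignment()
        tree = bootstrap_support(aln, n_replicates=100, seed=4)
        supports = [n.support_pct for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support_pct")]
        assert supports
        assert all(0 <= s <= 100 for s in supports)
        # the clade split {t0,t1,t2} | {t3,t4,t5} must be near-universal
        assert max(supports) >= 95

    def test_deterministic(self):
        aln = _clade_alignment()
        t1 = bootstrap_support(aln, n_replicates=50, seed=9)
        t2 = bootstrap_support(aln, n_replicates=50, seed=9)
        assert str(t1) == str(t2)

    def test_identical_sequences_star_like(self):
        aln = MultipleAlignment([f"t{i}" for i in range(4)], ["ACGT" * 30] * 4)
        tree = bootstrap_support(aln, n_replicates=20, seed=1)
        # metrically a star: all path lengths zero
        assert all((n.length or 0.0) == 0.0 for n in tree.traverse() if n.parent is not None)


class TestMidpointRoot:
    def test_two_leaves_even_split(self):
        t = TreeNode.read(["(A:1,B:3);"])
        rooted = midpoint_root(t)
        depths = sorted(tip.accumulate_to_ancestor(rooted) for tip in rooted.tips())
        assert depths == pytest.approx([2.0, 2.0])

    def test_caterpillar_diameter_oracle(self):
        t = TreeNode.read(["((((A:5,B:1):1,C:1):1,D:1):1,E:2);"])
        # all-pairs path oracle
        dm = t.tip_tip_distances()
        names = [x.name for x in t.tips()]
        diameter = max(
            dm[a, b] for i, a in enumerate(names) for b in names[i + 1:]
        )
        rooted = midpoint_root(t)
        deepest = max(tip.accumulate_to_ancestor(rooted) for tip in rooted.tips())
        assert deepest == pytest.approx(diameter / 2)

    def test_path_lengths_preserved(self):
        t = TreeNode.read(["((A:1,B:2):1.5,(C:0.5,D:3):0.5);"])
        before = t.tip_tip_distances().filter(list("ABCD"))
        rooted = midpoint_root(t)
        after = rooted.tip_tip_distances().filter(list("ABCD"))
        assert np.allclose(before.data, after.data, atol=1e-9)

    def test_zero_lengths_rejected(self):
        t = TreeNode.read(["((A:0,B:0):0,C:0);"])
        with pytest.raises(RootingError):
            midpoint_root(t)


class TestBlockFilter:
    def test_gap_free_unchanged(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT" * 10, "ACGT" * 10])
        res = conserved_block_filter(aln)
        assert res.alignment.rows == aln.rows
        assert res.n_blocks == 1

    def test_short_island_dropped(self):
        gappy = "-" * 20
        island = "ACGTA"
        rows = [gappy + island + gappy, gappy + island + gappy]
        # make one row gap in the flanks only
        rows[1] = "-" * 20 + island + "-" * 20
        aln = MultipleAlignment(["a", "b"], rows)
        res = conserved_block_filter(aln, min_block_length=10)
        assert res.alignment.length == 0
        assert res.n_blocks == 0

    def test_all_gap_column_removed(self):
        aln = MultipleAlignment(["a", "b"], ["ACGTACGTAC-ACGTACGTAC", "ACGTACGTAC-ACGTACGTAC"])
        res = conserved_block_filter(aln, min_block_length=5)
        assert res.alignment.length == 20
        assert res.n_blocks == 2

    def test_parameter_errors(self):
        aln = MultipleAlignment(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ParameterError):
            conserved_block_filter(aln, max_gap_fraction=1.5)
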