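"""Nei distances, PCA, MDS and neighbor joining."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from xstrkit import (
    mds_from_distances,
    nei_distance,
    nei_distance_matrix,
    nj_tree,
    pca_frequencies,
)
from xstrkit.core import AlleleFrequencyTable, LocusFrequencies


def _pop(freqs_by_locus):
    return AlleleFrequencyTable({
        locus: LocusFrequencies(list(fv), np.array(list(fv.values())))
        for locus, fv in freqs_by_locus.items()})


class TestNeiDistance:
    def test_identical_tables_zero(self):
        a = _pop({"L1": {"10": 0.6, "11": 0.4}, "L2": {"8": 1.0}})
        assert nei_distance(a, a) == 0.0

    def test_hand_computed_example(self):
        a = _pop({"L1": {"10": 0.6, "11": 0.4}})
        b = _pop({"L1": {"10": 0.5, "11": 0.5}})
        # J_A = 0.52, J_B = 0.5, J_AB = 0.5 -> I = 0.98058, D = 0.01961
        assert nei_distance(a, b) == pytest.approx(0.01961, abs=5e-6)

    def test_disjoint_allele_sets_infinite(self):
        a = _pop({"L1": {"10": 1.0}})
        b = _pop({"L1": {"11": 1.0}})
        with pytest.warns(UserWarning, match="infinite"):
            assert nei_distance(a, b) == np.inf

    def test_disjoint_locus_sets_error(self):
        a = _pop({"L1": {"10": 1.0}})
        b = _pop({"L2": {"10": 1.0}})
        with pytest.raises(ValueError, match="shared"):
            nei_distance(a, b)

    def test_matrix_symmetry_and_zero_diagonal(self, rng):
        pops = {}
        for i in range(5):
            pops[f"P{i}"] = _pop({
                "L1": dict(zip("abcd".upper(), rng.dirichlet([2, 2, 2, 2]))),
                "L2": dict(zip("ab".upper(), rng.dirichlet([3, 3]))),
            })
        dm = nei_distance_matrix(pops)
        assert np.allclose(dm.data, dm.data.T, atol=1e-12)
        assert np.all(np.diag(dm.data) == 0)
        assert np.all(dm.data >= 0)


class TestPca:
    def test_identical_populations_zero_variance(self):
        p = _pop({"L1": {"10": 0.6, "11": 0.4}})
        pops = {f"P{i}": p for i in range(4)}
        scores, _, pct = pca_frequencies(pops)
        assert np.allclose(scores.values, 0.0, atol=1e-12)

    def test_collinear_populations_single_component(self):
        pops = {}
        for i, x in enumerate((0.2, 0.4, 0.6)):
            pops[f"P{i}"] = _pop({"L1": {"10": x, "11": 1 - x}})
        _, _, pct = pca_frequencies(pops)
        assert pct[0] == pytest.approx(100.0)

    def test_percent_variance_sums_to_100(self, rng):
        pops = {f"P{i}": _pop({"L1": dict(zip("ABCD", rng.dirichlet([1] * 4))),
                               "L2": dict(zip("AB", rng.dirichlet([1, 1])))})
                for i in range(6)}
        _, _, pct = pca_frequencies(pops)
        assert pct.sum() == pytest.approx(100.0)

    def test_too_many_components_rejected(self, rng):
        pops = {f"P{i}": _pop({"L1": dict(zip("AB", rng.dirichlet([1, 1])))})
                for i in range(3)}
        with pytest.raises(ValueError):
            pca_frequencies(pops, components=5)


class TestMds:
    def test_recovers_planar_configuration(self, rng):
        pts = rng.random((6, 2)) * 10
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"P{i}" for i in range(6)])
        coords, stress = mds_from_distances(dm, dims=2)
        fitted = np.sqrt(((coords.values[:, None] - coords.values[None]) ** 2).sum(-1))
        np.testing.assert_allclose(fitted, d, atol=1e-9)
        assert stress == pytest.approx(0.0, abs=1e-9)

    def test_equilateral_triangle(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ids=list("ABC"))
        coords, _ = mds_from_distances(dm, dims=2)
        fitted = np.sqrt(((coords.values[:, None] - coords.values[None]) ** 2).sum(-1))
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(fitted[iu], 1.0, atol=1e-9)

    def test_two_populations_single_axis(self):
        dm = DistanceMatrix(np.array([[0, 2.5], [2.5, 0]]), ids=["A", "B"])
        coords, stress = mds_from_distances(dm, dims=1)
        assert abs(coords.values[0, 0] - coords.values[1, 0]) == pytest.approx(2.5)
        assert stress == pytest.approx(0.0, abs=1e-12)

    def test_dims_bounds(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=["A", "B"])
        with pytest.raises(ValueError):
            mds_from_distances(dm, dims=2)


def _tree_distance_matrix(tree, ids):
    m = np.zeros((len(ids), len(ids)))
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            d = tree.find(a).distance(tree.find(ids[j]))
            m[i, j] = m[j, i] = d
    return DistanceMatrix(m, ids=ids)


class TestNeighborJoining:
    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(np.array([[0, 5, 9], [5, 0, 8], [9, 8, 0]], float),
                            ids=list("ABC"))
        t = nj_tree(dm)
        # l_A = (5+9-8)/2 = 3, l_B = 2, l_C = 6
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths == {"A": 3.0, "B": 2.0, "C": 6.0}

    def test_additive_five_taxon_recovery(self):
        ref = DistanceMatrix(np.zeros((5, 5)), ids=list("ABCDE"))
        # fixed generating tree ((A:2,B:3):1,(C:1,D:4):2,E:5)
        paths = {("A", "B"): 5, ("A", "C"): 6, ("A", "D"): 9, ("A", "E"): 8,
                 ("B", "C"): 7, ("B", "D"): 10, ("B", "E"): 9, ("C", "D"): 5,
                 ("C", "E"): 8, ("D", "E"): 11}
        m = np.zeros((5, 5))
        ids = list("ABCDE")
        for (a, b), v in paths.items():
            i, j = ids.index(a), ids.index(b)
            m[i, j] = m[j, i] = v
        t = nj_tree(DistanceMatrix(m, ids=ids))
        for (a, b), v in paths.items():
            assert t.find(a).distance(t.find(b)) == pytest.approx(v, abs=1e-9)

    def test_ultrametric_four_taxon_split(self):
        # ((A,B),(C,D)) with within-pair distance 2, across 6
        m = np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]],
                     dtype=float)
        t = nj_tree(DistanceMatrix(m, ids=list("ABCD")))
        ab = t.lowest_common_ancestor(["A", "B"])
        assert {tip.name for tip in ab.tips()} in ({"A", "B"}, {"C", "D"})

    def test_random_additive_trees_recovered(self, rng):
        """NJ is exact on additive matrices (random trees, <= 8 leaves)."""
        from skbio import TreeNode

        for rep in range(10):
            n = int(rng.integers(4, 9))
            ids = [f"T{i}" for i in range(n)]
            # random binary tree by sequential attachment, positive lengths
            tree = TreeNode.read(
                [f"({ids[0]}:{rng.uniform(0.5, 2):.4f},{ids[1]}:{rng.uniform(0.5, 2):.4f});"])
            for name in ids[2:]:
                tips = list(tree.tips())
                target = tips[rng.integers(len(tips))]
                old_len = target.length
                split = TreeNode(length=old_len / 2)
                parent = target.parent
                parent.remove(target)
                target.length = old_len / 2
                split.append(target)
                split.append(TreeNode(name=name, length=float(rng.uniform(0.5, 2))))
                parent.append(split)
            dm = _tree_distance_matrix(tree, ids)
            t = nj_tree(dm)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    assert t.find(a).distance(t.find(b)) == pytest.approx(
                        dm[a, b], abs=1e-9)

    def test_agrees_with_reference_implementation(self, rng):
        """Topology cross-check against the scikit-bio NJ on a random matrix."""
        n = 6
        pts = rng.random((n, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"P{i}" for i in range(n)])
        ours = nj_tree(dm)
        theirs = skbio_nj(dm)
        assert ours.compare_rfd(theirs) == 0.0

    def test_requires_three_taxa(self):
        dm = DistanceMatrix(np.array([[0, 1], [1, 0]], float), ids=["A", "B"])
        with pytest.raises(ValueError):
            nj_tree(dm)


def test_pipeline_coherence_distance_to_mds_and_tree(rng):
    """The same Nei matrix feeds MDS and NJ."""
    pops = {f"P{i}": _pop({"L1": dict(zip("ABC", rng.dirichlet([2, 2, 2]))),
                           "L2": dict(zip("AB", rng.dirichlet([2, 2])))})
            for i in range(5)}
    dm = nei_distance_matrix(pops)
    coords, stress = mds_from_distances(dm, dims=2)
    tree = nj_tree(dm)
    assert list(coords.index) == list(dm.ids)
    assert {t.name for t in tree.tips()} == set(dm.ids)
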