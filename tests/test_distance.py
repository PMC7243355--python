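"""Dissimilarities, weighted UniFrac, NMDS, hierarchical clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from skbio import DistanceMatrix

from otunet import (
    bray_curtis,
    generate_basis_table,
    generate_tree,
    hierarchical_cluster,
    importance_profiles,
    jaccard,
    nmds,
    weighted_unifrac,
)


def profiles(rows, index=None, columns=None):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr,
        index=index or [f"e{i}" for i in range(arr.shape[0])],
        columns=columns or [f"f{j}" for j in range(arr.shape[1])],
    )


class TestBrayCurtis:
    def test_identical_profiles_zero(self):
        d = bray_curtis(profiles([[1, 2, 3], [1, 2, 3]]))
        assert d.data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = bray_curtis(profiles([[1, 1, 0, 0], [0, 0, 2, 3]]))
        assert d.data[0, 1] == 1.0

    def test_hand_example(self):
        d = bray_curtis(profiles([[1, 1, 0], [0, 1, 1]]))
        assert d.data[0, 1] == pytest.approx(0.5)

    def test_all_zero_profile_named_in_error(self):
        with pytest.raises(ValueError, match="e1"):
            bray_curtis(profiles([[1, 1], [0, 0]]))


class TestJaccard:
    def test_identical_supports_zero(self):
        d = jaccard(profiles([[5, 1, 0], [2, 9, 0]]))
        assert d.data[0, 1] == 0.0

    def test_disjoint_supports_one(self):
        d = jaccard(profiles([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert d.data[0, 1] == 1.0

    def test_half_overlap(self):
        # supports {a,b,c} vs {b,c,d}: intersection 2, union 4
        d = jaccard(profiles([[1, 1, 1, 0], [0, 1, 1, 1]]))
        assert d.data[0, 1] == pytest.approx(0.5)


class TestMetricProperties:
    @pytest.mark.parametrize("fn", [bray_curtis, jaccard])
    def test_fuzz_identity_symmetry_range(self, fn, rng):
        """1,000 random profile pairs: d(x,x)=0, symmetry, entries in [0,1]."""
        for _ in range(100):
            prof = profiles(rng.integers(0, 20, size=(10, 15)) * rng.integers(0, 2, size=(10, 15)))
            prof = prof[prof.sum(axis=1) > 0]
            if prof.shape[0] < 2:
                continue
            d = fn(prof).data
            assert np.abs(d - d.T).max() == 0.0
            assert np.allclose(np.diag(d), 0.0)
            assert (d >= 0).all() and (d <= 1.0 + 1e-12).all()


def naive_unifrac_oracle(prof, tree, normalized):
    """Per-branch summation using each node's own leaf subset (independent
    of the matrix-based implementation route)."""
    rel = prof.div(prof.sum(axis=1), axis=0)
    out = np.zeros((len(prof), len(prof)))
    for a, b in itertools.combinations(range(len(prof)), 2):
        num = den = 0.0
        for node in tree.postorder(include_self=False):
            leaves = {t.name for t in node.tips()} or {node.name}
            pa = rel.iloc[a][[c for c in prof.columns if c in leaves]].sum()
            pb = rel.iloc[b][[c for c in prof.columns if c in leaves]].sum()
            num += node.length * abs(pa - pb)
            den += node.length * (pa + pb)
        out[a, b] = out[b, a] = num / den if normalized else num
    return out


class TestWeightedUnifrac:
    def test_identical_profiles_zero(self):
        tree = generate_tree(["f0", "f1", "f2"], seed=0)
        d = weighted_unifrac(profiles([[1, 2, 3], [2, 4, 6]]), tree)
        assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_two_leaf_cherry_disjoint_is_one(self):
        from skbio import TreeNode

        tree = TreeNode.read(["(f0:1,f1:1);"])
        d = weighted_unifrac(profiles([[1, 0], [0, 1]]), tree, normalized=True)
        assert d.data[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("normalized", [True, False])
    @pytest.mark.parametrize("seed", [1, 2])
    def test_matches_naive_per_branch_oracle(self, normalized, seed, rng):
        cols = [f"f{i}" for i in range(8)]
        tree = generate_tree(cols, seed=seed)
        prof = profiles(rng.integers(1, 50, size=(5, 8)), columns=cols)
        d = weighted_unifrac(prof, tree, normalized=normalized)
        oracle = naive_unifrac_oracle(prof, tree, normalized)
        assert np.abs(d.data - oracle).max() < 1e-12

    def test_star_tree_proportional_to_l1(self):
        """All leaves at equal depth directly off the root: raw W equals
        depth x L1 distance of relative abundances."""
        from skbio import TreeNode

        tree = TreeNode.read(["(f0:2,f1:2,f2:2,f3:2);"])
        prof = profiles([[4, 3, 2, 1], [1, 1, 4, 4]])
        rel = prof.div(prof.sum(axis=1), axis=0).to_numpy()
        l1 = np.abs(rel[0] - rel[1]).sum()
        d = weighted_unifrac(prof, tree, normalized=False)
        assert d.data[0, 1] == pytest.approx(2.0 * l1, abs=1e-12)

    def test_missing_otu_listed(self):
        tree = generate_tree(["f0", "f1"], seed=3)
        with pytest.raises(ValueError, match="f2"):
            weighted_unifrac(profiles([[1, 2, 3], [3, 2, 1]]), tree)


class TestNmds:
    def test_euclidean_configuration_recovered(self, rng):
        pts = rng.standard_normal((10, 2))
        d = DistanceMatrix(
            squareform(np.round(np.linalg.norm(pts[:, None] - pts[None], axis=-1), 12)),
            ids=[str(i) for i in range(10)],
        )
        coords, stress = nmds(d, k=2, n_starts=4, seed=0)
        assert stress < 0.01

    def test_more_iterations_never_worse(self):
        table, _ = generate_basis_table(12, 20, seed=61)
        d = bray_curtis(table)
        _, s_short = nmds(d, k=2, n_starts=1, seed=3, max_iter=5)
        _, s_long = nmds(d, k=2, n_starts=1, seed=3, max_iter=300)
        assert s_long <= s_short + 1e-12

    def test_rank_order_of_fitted_distances(self):
        """4-point configuration: fitted distances reproduce the rank order
        of the input dissimilarities (what 'non-metric' promises)."""
        d = DistanceMatrix(
            np.array(
                [[0, 1, 4, 9], [1, 0, 2, 7], [4, 2, 0, 3], [9, 7, 3, 0]], dtype=float
            ),
            ids=list("abcd"),
        )
        coords, stress = nmds(d, k=2, n_starts=8, seed=1)
        fitted = squareform(
            np.linalg.norm(coords.to_numpy()[:, None] - coords.to_numpy()[None], axis=-1),
            checks=False,
        )
        rho, _ = spearmanr(fitted, squareform(d.data, checks=False))
        assert rho == pytest.approx(1.0)

    def test_deterministic(self):
        table, _ = generate_basis_table(10, 15, seed=67)
        d = bray_curtis(table)
        c1, s1 = nmds(d, n_starts=3, seed=9)
        c2, s2 = nmds(d, n_starts=3, seed=9)
        assert s1 == s2 and c1.equals(c2)

    def test_k_too_large(self):
        d = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nmds(d, k=2)


def naive_upgma_cophenetic(dmat, labels):
    """O(n^3) average-linkage agglomeration; returns cophenetic matrix."""
    clusters = {i: [i] for i in range(len(labels))}
    dist = {frozenset((a, b)): dmat[a, b] for a in range(len(labels)) for b in range(a)}
    coph = np.zeros_like(dmat)
    nxt = len(labels)
    while len(clusters) > 1:
        (a, b), h = min(
            ((tuple(sorted(k)), v) for k, v in dist.items() if len(k) == 2),
            key=lambda kv: kv[1],
        )
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        merged = clusters[a] + clusters[b]
        del dist[frozenset((a, b))]
        for c in list(clusters):
            if c in (a, b):
                continue
            da = dist.pop(frozenset((a, c)))
            db = dist.pop(frozenset((b, c)))
            na, nb = len(clusters[a]), len(clusters[b])
            dist[frozenset((nxt, c))] = (na * da + nb * db) / (na + nb)
        del clusters[a], clusters[b]
        clusters[nxt] = merged
        nxt += 1
    return coph


class TestHierarchicalCluster:
    def test_first_merge_is_closest_pair(self):
        d = DistanceMatrix(
            np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float), ids=list("abc")
        )
        dend = hierarchical_cluster(d)
        assert dend.heights()[0] == 1.0
        first = sorted(int(x) for x in dend.merges[0, :2])
        assert [dend.labels[i] for i in first] == ["a", "b"]

    def test_scale_equivariance(self, rng):
        arr = squareform(rng.random(15))
        ids = [f"s{i}" for i in range(6)]
        d1 = hierarchical_cluster(DistanceMatrix(arr, ids=ids))
        d2 = hierarchical_cluster(DistanceMatrix(2 * arr, ids=ids))
        assert np.allclose(d2.heights(), 2 * d1.heights())
        assert np.array_equal(d1.merges[:, :2], d2.merges[:, :2])

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_naive_agglomeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = squareform(rng.random(15))
        ids = [f"s{i}" for i in range(6)]
        dend = hierarchical_cluster(DistanceMatrix(arr, ids=ids))
        coph = squareform(cophenet(dend.merges))
        oracle = naive_upgma_cophenetic(arr, ids)
        assert np.abs(coph - oracle).max() < 1e-12

    def test_heights_nondecreasing(self, rng):
        arr = squareform(rng.random(45))
        d = DistanceMatrix(arr, ids=[f"s{i}" for i in range(10)])
        h = hierarchical_cluster(d).heights()
        assert (np.diff(h) >= -1e-12).all()

    def test_newick_roundtrip_leaf_set(self):
        from skbio import TreeNode
        import io

        d = DistanceMatrix(
            np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float), ids=list("abc")
        )
        nwk = hierarchical_cluster(d).to_newick()
        tree = TreeNode.read(io.StringIO(nwk))
        assert sorted(t.name for t in tree.tips()) == ["a", "b", "c"]

    def test_unknown_linkage(self):
        d = DistanceMatrix(np.array([[0, 1.0], [1.0, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError, match="linkage"):
            hierarchical_cluster(d, linkage="centroid")


class TestProfiles:
    def test_absent_otu_zero_and_pagerank_rows_sum_to_one(self):
        nets = {
            "g1": pd.Series({"a": 0.6, "b": 0.4}, name="pagerank"),
            "g2": pd.Series({"b": 0.3, "c": 0.7}, name="pagerank"),
        }
        prof = importance_profiles(nets)
        assert prof.loc["g1", "c"] == 0.0
        assert np.allclose(prof.sum(axis=1), 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            importance_profiles({"g1": pd.Series({"a": 1.0})})

    def test_jaccard_on_profiles_reflects_support_overlap(self):
        nets = {
            "g1": pd.Series({"a": 0.5, "b": 0.5}),
            "g2": pd.Series({"b": 0.5, "c": 0.5}),
        }
        d = jaccard(importance_profiles(nets))
        assert d.data[0, 1] == pytest.approx(1 - 1 / 3)
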