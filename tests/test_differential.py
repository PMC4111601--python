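import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage

from trioma.data import Channel, Condition, ExpressionMatrix, SampleDesign, SLRMatrix
from trioma.differential import call_differential, cut_tree, hierarchical_cluster


def slr_from_rows(rows, design):
    df = pd.DataFrame(
        np.asarray(rows, dtype=float),
        index=[f"p{i}" for i in range(len(rows))],
        columns=design.sample_ids,
    )
    return SLRMatrix(data=df, design=design)


def naive_average_linkage(X):
    """O(n^3) agglomeration oracle: recompute all pairwise cluster-average
    distances from scratch at every step."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = np.mean(
                [
                    np.linalg.norm(X[i] - X[j])
                    for i in clusters[a]
                    for j in clusters[b]
                ]
            )
            leaves = sorted(clusters[a] + clusters[b])
            key = (d, leaves[0], leaves[-1])
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _, _), a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, d, len(clusters[next_id])))
        next_id += 1
    return merges


class TestCallDifferential:
    def test_single_excursion_calls_de(self, maturation_design):
        slr = slr_from_rows([[0, 0.5, 1.2, 0.8]], maturation_design)
        (call,) = call_differential(slr, cut=1.0)
        assert call.is_de
        assert call.direction == ("flat", "flat", "up", "flat")

    def test_cut_is_strict(self, maturation_design):
        slr = slr_from_rows([[0, -1.0, -1.0, -1.0]], maturation_design)
        (call,) = call_differential(slr, cut=1.0)
        assert not call.is_de

    def test_monotone_in_cut(self, maturation_design, rng):
        rows = rng.normal(0, 1.5, size=(40, 4))
        rows[:, 0] = 0.0
        slr = slr_from_rows(rows, maturation_design)
        flags = {}
        for cut in (0.5, 1.0, 1.5, 2.0):
            flags[cut] = [c.is_de for c in call_differential(slr, cut)]
        for lo, hi in zip((0.5, 1.0, 1.5), (1.0, 1.5, 2.0)):
            for a, b in zip(flags[lo], flags[hi]):
                assert a or not b  # raising the cut never creates a DE call

    def test_empty_matrix_gives_empty_list(self, maturation_design):
        slr = slr_from_rows(np.empty((0, 4)), maturation_design)
        assert call_differential(slr, cut=1.0) == []


class TestHierarchicalCluster:
    def test_three_point_line(self):
        tree = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
        (a, b, h1, s1), (_, _, h2, s2) = tree.merges
        assert {a, b} == {0, 1} and h1 == 1.0 and s1 == 2
        assert h2 == pytest.approx(9.5) and s2 == 3

    def test_identical_profiles_merge_first_at_zero(self):
        tree = hierarchical_cluster(np.array([[3.0, 1.0], [0.0, 0.0], [3.0, 1.0]]))
        a, b, h, _ = tree.merges[0]
        assert {a, b} == {0, 2} and h == 0.0

    def test_tree_shape_and_monotone_heights(self, rng):
        X = rng.normal(size=(9, 3))
        tree = hierarchical_cluster(X)
        assert tree.n_leaves == 9 and len(tree.merges) == 8
        assert np.all(np.diff(tree.heights) >= -1e-12)

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_naive_oracle_on_small_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 9))
        X = rng.normal(size=(n, int(rng.integers(1, 4))))
        tree = hierarchical_cluster(X)
        oracle = naive_average_linkage(X)
        for (a, b, h, s), (oa, ob, oh, os) in zip(tree.merges, oracle):
            assert {a, b} == {oa, ob}
            assert h == pytest.approx(oh)
            assert s == os

    def test_matches_scipy_average_linkage_heights(self, rng):
        X = rng.normal(size=(15, 4))
        ours = hierarchical_cluster(X).to_linkage()
        theirs = linkage(X, method="average", metric="euclidean")
        assert np.allclose(sorted(ours[:, 2]), sorted(theirs[:, 2]))

    def test_permutation_invariant_heights(self, rng):
        X = rng.normal(size=(8, 2))
        perm = rng.permutation(8)
        h1 = sorted(hierarchical_cluster(X).heights)
        h2 = sorted(hierarchical_cluster(X[perm]).heights)
        assert np.allclose(h1, h2)

    def test_samples_axis_clusters_columns(self, maturation_design):
        rows = [[0, 0.1, 2.0, 2.1], [0, -0.1, -2.0, -2.2]]
        df = pd.DataFrame(rows, index=["a", "b"], columns=maturation_design.sample_ids)
        slr = SLRMatrix(data=df, design=maturation_design)
        tree = hierarchical_cluster(slr, on="samples")
        assert tree.n_leaves == 4
        labels = cut_tree(tree, 2)
        # late timepoints separate from the early ones
        assert labels["Day6"] == labels["Day8"] != labels["Day2"] == labels["Day4"]

    def test_fewer_than_two_items_is_an_error(self):
        with pytest.raises(ValueError, match=">=2"):
            hierarchical_cluster(np.array([[1.0]]))


class TestCutTree:
    def test_two_clusters_split_far_point(self):
        tree = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
        labels = cut_tree(tree, 2)
        assert labels["0"] == labels["1"] != labels["2"]

    def test_extremes(self):
        tree = hierarchical_cluster(np.array([[0.0], [1.0], [10.0]]))
        assert set(cut_tree(tree, 3).values()) == {0, 1, 2}
        assert set(cut_tree(tree, 1).values()) == {0}

    def test_tied_heights_make_counts_unreachable(self):
        tree = hierarchical_cluster(np.array([[0.0], [0.0], [10.0], [10.0]]))
        # both zero-height merges happen "at once": 3 clusters unreachable
        with pytest.raises(ValueError, match="achievable"):
            cut_tree(tree, 3)
        assert len(set(cut_tree(tree, 2).values())) == 2
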