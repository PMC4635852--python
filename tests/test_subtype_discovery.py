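import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_score

from oracles import brute_connectivity, brute_dunn, brute_silhouette
from txsubtypes.subtype_discovery import (
    classical_mds,
    connectivity_index,
    cut_tree,
    dunn_index,
    flag_outliers,
    hierarchical_cluster,
    pairwise_distances,
    select_k,
    silhouette_index,
)


def _dist(points):
    return squareform(pdist(np.asarray(points, dtype=float)))


class TestClassicalMDS:
    def test_collinear_points_recovered_in_1d(self):
        points = np.array([[0.0], [1.0], [2.0], [3.0]])
        coords = classical_mds(_dist(points), d=1)
        np.testing.assert_allclose(_dist(coords), _dist(points), atol=1e-9)

    def test_equilateral_triangle_in_2d(self):
        dist = np.ones((3, 3)) - np.eye(3)
        coords = classical_mds(dist, d=2)
        np.testing.assert_allclose(_dist(coords), dist, atol=1e-9)

    @pytest.mark.parametrize("n,dim", [(6, 2), (10, 3), (25, 5)])
    def test_euclidean_input_embeds_with_zero_stress(self, n, dim):
        rng = np.random.default_rng(n * dim)
        points = rng.normal(size=(n, dim))
        coords = classical_mds(_dist(points), d=dim)
        np.testing.assert_allclose(_dist(coords), _dist(points), atol=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]), d=1)
        with pytest.raises(ValueError, match="negative"):
            classical_mds(np.array([[0.0, -1.0], [-1.0, 0.0]]), d=1)

    def test_non_euclidean_axes_zeroed_with_warning(self):
        # gross triangle-inequality violation -> negative eigenvalues
        dist = np.array([
            [0.0, 10.0, 1.0, 1.0],
            [10.0, 0.0, 1.0, 1.0],
            [1.0, 1.0, 0.0, 1.0],
            [1.0, 1.0, 1.0, 0.0],
        ])
        with pytest.warns(UserWarning, match="negative"):
            coords = classical_mds(dist, d=4)
        assert np.allclose(coords[:, -1], 0.0)


class TestOutlierFlagging:
    def test_single_far_sample_flagged(self):
        rng = np.random.default_rng(0)
        coords = np.vstack([rng.normal(0, 1, size=(20, 2)), [[50.0, 0.0]]])
        ids = [f"s{i}" for i in range(21)]
        report = flag_outliers(coords, ids)
        assert report.outliers == {"s20"}
        assert math.isclose(report.zscore.mean(), 0.0, abs_tol=1e-12)
        assert math.isclose(report.zscore.std(ddof=1), 1.0, rel_tol=1e-12)

    def test_identical_coordinates_degenerate(self):
        coords = np.ones((5, 2))
        report = flag_outliers(coords, list("abcde"))
        assert report.degenerate and report.outliers == set()

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        coords = np.vstack([rng.normal(0, 1, size=(15, 2)), [[30.0, -5.0]]])
        ids = [f"s{i}" for i in range(16)]
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = coords @ rot.T + np.array([100.0, -3.0])
        a = flag_outliers(coords, ids)
        b = flag_outliers(moved, ids)
        assert a.outliers == b.outliers
        np.testing.assert_allclose(a.distance, b.distance, atol=1e-9)

    def test_centroid_mode_and_small_n_rejected(self):
        coords = np.array([[0.0, 0], [1, 0], [0, 1], [10, 10]])
        report = flag_outliers(coords, list("abcd"), center_mode="centroid")
        assert report.center_mode == "centroid"
        with pytest.raises(ValueError, match="4 samples"):
            flag_outliers(coords[:3], list("abc"))
        with pytest.raises(ValueError, match="center_mode"):
            flag_outliers(coords, list("abcd"), center_mode="mean")


class TestHierarchy:
    SEPARATED_PAIRS = np.array([[0.0, 0], [0.1, 0], [10, 0], [10.1, 0]])

    def test_separated_pairs_merge_first(self):
        tree = hierarchical_cluster(self.SEPARATED_PAIRS, "euclidean", "average")
        first_two = {frozenset(map(int, row[:2])) for row in tree[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_cut_at_two_recovers_planted_split(self):
        tree = hierarchical_cluster(self.SEPARATED_PAIRS, "euclidean", "average")
        assert list(cut_tree(tree, 2)) == [1, 1, 2, 2]

    @pytest.mark.parametrize("linkage", ["average", "complete"])
    def test_merge_heights_monotone(self, linkage):
        rng = np.random.default_rng(8)
        for _ in range(100):
            obs = rng.normal(size=(rng.integers(4, 15), 3))
            tree = hierarchical_cluster(obs, "euclidean", linkage)
            heights = tree[:, 2]
            assert np.all(np.diff(heights) >= -1e-12)

    def test_ward_requires_euclidean(self):
        with pytest.raises(ValueError, match="euclidean"):
            hierarchical_cluster(self.SEPARATED_PAIRS, "one_minus_pearson", "ward")

    def test_cut_tree_bounds_and_trivial_cuts(self):
        tree = hierarchical_cluster(self.SEPARATED_PAIRS, "euclidean", "average")
        assert list(cut_tree(tree, 1)) == [1, 1, 1, 1]
        assert sorted(cut_tree(tree, 4)) == [1, 2, 3, 4]
        assert cut_tree(tree, 4)[0] == 1  # first sample anchors cluster 1
        for bad in (0, 5):
            with pytest.raises(ValueError):
                cut_tree(tree, bad)

    def test_cuts_agree_with_explicit_merge_replay(self):
        """Replaying merges by hand must reproduce every cut's partition."""
        rng = np.random.default_rng(17)
        obs = rng.normal(size=(12, 4))
        tree = hierarchical_cluster(obs, "euclidean", "average")
        n = obs.shape[0]
        clusters = {i: {i} for i in range(n)}
        partitions = {n: {frozenset(c) for c in clusters.values()}}
        for step, (a, b, _, _) in enumerate(tree):
            new = clusters.pop(int(a)) | clusters.pop(int(b))
            clusters[n + step] = new
            partitions[n - step - 1] = {frozenset(c) for c in clusters.values()}
        for k in range(1, n + 1):
            labels = cut_tree(tree, k)
            got = {frozenset(np.flatnonzero(labels == lab))
                   for lab in set(labels)}
            assert got == partitions[k], f"k={k}"


class TestValidityIndices:
    def test_connectivity_zero_for_separated_clusters(self):
        points = np.vstack([np.random.default_rng(1).normal(0, 0.1, (5, 2)),
                            np.random.default_rng(2).normal(50, 0.1, (5, 2))])
        labels = [1] * 5 + [2] * 5
        assert connectivity_index(_dist(points), labels, L=4) == 0.0

    def test_connectivity_all_singletons_hand_value(self):
        dist = _dist([[0.0], [1.0], [2.0]])
        assert connectivity_index(dist, [1, 2, 3], L=2) == pytest.approx(4.5)

    def test_dunn_hand_value_and_overlap(self):
        dist = _dist([[0.0], [1.0], [10.0], [11.0]])
        assert dunn_index(dist, [1, 1, 2, 2]) == pytest.approx(9.0)
        # interleaved clusters: diameter exceeds separation
        assert dunn_index(dist, [1, 2, 1, 2]) < 1.0

    def test_dunn_all_singletons_infinite(self):
        dist = _dist([[0.0], [1.0], [5.0]])
        assert math.isinf(dunn_index(dist, [1, 2, 3]))

    def test_silhouette_limits(self):
        tight = np.vstack([np.zeros((4, 1)), np.full((4, 1), 1000.0)])
        tight += np.linspace(0, 1, 8)[:, None] * 0.5
        labels = [1] * 4 + [2] * 4
        assert silhouette_index(_dist(tight), labels) >= 0.99

    def test_silhouette_near_zero_for_random_labels(self):
        rng = np.random.default_rng(12)
        vals = []
        for _ in range(50):
            points = rng.normal(size=(12, 2))
            labels = rng.integers(1, 3, size=12)
            if len(set(labels)) < 2:
                continue
            vals.append(silhouette_index(_dist(points), labels))
        assert abs(np.mean(vals)) < 0.1

    def test_silhouette_matches_sklearn_without_singletons(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            points = rng.normal(size=(10, 3))
            labels = np.array([1] * 5 + [2] * 5)
            dist = _dist(points)
            assert silhouette_index(dist, labels) == pytest.approx(
                silhouette_score(dist, labels, metric="precomputed"))

    @pytest.mark.parametrize("index,oracle", [
        (lambda d, l: connectivity_index(d, l, L=5),
         lambda d, l: brute_connectivity(d, l, 5)),
        (dunn_index, brute_dunn),
        (silhouette_index, brute_silhouette),
    ], ids=["connectivity", "dunn", "silhouette"])
    def test_indices_match_brute_force_on_random_instances(self, index, oracle):
        rng = np.random.default_rng(99)
        for _ in range(60):
            n = int(rng.integers(4, 13))
            points = rng.normal(size=(n, 2))
            k = int(rng.integers(2, min(n, 5)))
            labels = np.concatenate([np.arange(1, k + 1),
                                     rng.integers(1, k + 1, size=n - k)])
            rng.shuffle(labels)
            dist = _dist(points)
            assert index(dist, labels) == pytest.approx(oracle(dist, labels))


class TestSelectK:
    def test_three_blobs_select_three(self):
        rng = np.random.default_rng(5)
        obs = np.vstack([rng.normal(c, 0.3, size=(8, 2))
                         for c in ((0, 0), (20, 0), (0, 20))])
        tree = hierarchical_cluster(obs, "euclidean", "average")
        dist = pairwise_distances(obs, "euclidean")
        solution = select_k(dist, tree, range(2, 7))
        # connectivity cannot separate k=2 from k=3 here: with L=10 > blob
        # size every neighborhood stays inside the merged cluster, so it
        # ties/falls toward smaller k; Dunn and silhouette carry the vote
        assert solution.selected_k == 3
        assert solution.selection_votes["dunn"] == 3
        assert solution.selection_votes["silhouette"] == 3

    def test_single_candidate_k_trivial(self):
        rng = np.random.default_rng(6)
        obs = rng.normal(size=(8, 2))
        tree = hierarchical_cluster(obs, "euclidean", "average")
        dist = pairwise_distances(obs, "euclidean")
        solution = select_k(dist, tree, [2])
        assert solution.selected_k == 2
        assert set(solution.selection_votes.values()) == {2}

    def test_empty_k_range_rejected(self):
        rng = np.random.default_rng(7)
        obs = rng.normal(size=(6, 2))
        tree = hierarchical_cluster(obs, "euclidean", "average")
        with pytest.raises(ValueError, match="empty"):
            select_k(pairwise_distances(obs, "euclidean"), tree, [])

    def test_partitions_are_complete_and_sized(self):
        rng = np.random.default_rng(13)
        obs = rng.normal(size=(15, 4))
        tree = hierarchical_cluster(obs, "one_minus_pearson", "average")
        dist = pairwise_distances(obs, "one_minus_pearson")
        solution = select_k(dist, tree, range(2, 7))
        for k, labels in solution.labels_by_k.items():
            assert len(set(labels)) == k and len(labels) == 15
        assert solution.selected_k in solution.labels_by_k
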