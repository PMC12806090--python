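import numpy as np
import pytest
from numpy.testing import assert_allclose
from scipy.stats import spearmanr

from stmodules.ihc_cluster import (
    ClusterError,
    ClusterState,
    compute_centers,
    cut_hierarchy,
    iterate_to_convergence,
    make_alpha_grid,
    merge_step,
    prune_step,
    run_stihc,
    silhouette_scores,
    spearman_distance,
    _spearman_matrix,
)


def brute_average_linkage(dist, threshold):
    """O(G^3) sequential agglomeration oracle: merge the closest pair of
    clusters (average linkage, distance = mean over all cross pairs)
    while that distance is <= threshold.  Tied pairs resolve toward the
    clusters containing the smallest gene indices."""
    clusters = [[i] for i in range(dist.shape[0])]
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                key = (d, min(clusters[a] + clusters[b]),
                       max(min(clusters[a]), min(clusters[b])))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, *_), a, b = best
        if d > threshold:
            break
        clusters[a] = sorted(clusters[a] + clusters[b])
        del clusters[b]
    labels = np.empty(dist.shape[0], dtype=int)
    for k, members in enumerate(clusters):
        labels[members] = k
    return labels


def partitions_equal(a, b):
    a, b = np.asarray(a), np.asarray(b)
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


@pytest.fixture
def two_group_coeffs():
    """10 + 10 genes from two rank-distinct smooth profiles plus jitter."""
    rng = np.random.default_rng(0)
    K = 30
    t = np.linspace(0, 1, K)
    base1, base2 = np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)
    rows = [base1 + 0.01 * rng.normal(size=K) for _ in range(10)]
    rows += [base2 + 0.01 * rng.normal(size=K) for _ in range(10)]
    return np.vstack(rows)


class TestSpearmanDistance:
    def test_identical_rows(self):
        C = np.vstack([[1.0, 2.0, 3.0, 4.0]] * 2)
        gd = spearman_distance(C)
        assert_allclose(gd.rho[0, 1], 1.0)
        assert_allclose(gd.dist[0, 1], 0.0)

    def test_rank_reversal(self):
        C = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        gd = spearman_distance(C)
        assert_allclose(gd.rho[0, 1], -1.0)
        assert_allclose(gd.dist[0, 1], 2.0)

    def test_hand_case(self):
        # Spearman sum-of-squared-rank-differences formula:
        # rho = 1 - 6*2/(3*8) = 0.5
        C = np.array([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]])
        gd = spearman_distance(C)
        assert_allclose(gd.rho[0, 1], 0.5)
        assert_allclose(gd.dist[0, 1], 0.5)

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        C = rng.normal(size=(6, 11))
        gd = spearman_distance(C)
        oracle = spearmanr(C, axis=1).statistic
        assert_allclose(gd.rho, oracle, atol=1e-12)

    def test_constant_row_raises_with_name(self):
        C = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ClusterError, match="geneA"):
            spearman_distance(C, gene_ids=("geneA", "geneB"))

    def test_alpha_extremes(self):
        rng = np.random.default_rng(2)
        C = rng.normal(size=(5, 9))
        gd = spearman_distance(C)
        off = gd.rho[~np.eye(5, dtype=bool)]
        assert gd.alpha_min == pytest.approx(off.min())
        assert gd.alpha_max == pytest.approx(off.max())


class TestAlphaGrid:
    def test_equally_spaced(self):
        gd = spearman_distance(np.random.default_rng(3).normal(size=(4, 8)))
        object.__setattr__(gd, "alpha_min", 0.0)
        object.__setattr__(gd, "alpha_max", 1.0)
        assert_allclose(make_alpha_grid(gd, 5), [0, 0.25, 0.5, 0.75, 1.0])

    def test_two_points_are_endpoints(self):
        gd = spearman_distance(np.random.default_rng(4).normal(size=(4, 8)))
        grid = make_alpha_grid(gd, 2)
        assert_allclose(grid, [gd.alpha_min, gd.alpha_max])

    def test_degenerate_span_warns(self):
        C = np.vstack([[1.0, 2.0, 3.0]] * 3)
        gd = spearman_distance(C)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            grid = make_alpha_grid(gd, 7)
        assert grid.shape == (1,)

    def test_rejects_zero(self):
        gd = spearman_distance(np.random.default_rng(5).normal(size=(4, 8)))
        with pytest.raises(ClusterError):
            make_alpha_grid(gd, 0)


class TestCutHierarchy:
    def test_identical_genes_one_cluster(self):
        dist = np.zeros((3, 3))
        labels = cut_hierarchy(dist, alpha=0.9)
        assert len(set(labels)) == 1

    def test_two_tight_groups(self):
        dist = np.full((4, 4), 2.0)
        np.fill_diagonal(dist, 0.0)
        dist[0, 1] = dist[1, 0] = 0.01
        dist[2, 3] = dist[3, 2] = 0.01
        labels = cut_hierarchy(dist, alpha=0.5)
        assert partitions_equal(labels, [0, 0, 1, 1])

    @pytest.mark.parametrize("seed", range(20))
    @pytest.mark.parametrize("alpha", [-0.5, 0.0, 0.3, 0.7])
    def test_matches_brute_force_oracle(self, seed, alpha):
        rng = np.random.default_rng(seed)
        G = int(rng.integers(3, 9))
        C = rng.normal(size=(G, 7))
        dist = spearman_distance(C).dist
        labels = cut_hierarchy(dist, alpha)
        oracle = brute_average_linkage(dist, 1.0 - alpha)
        assert partitions_equal(labels, oracle)

    def test_labels_first_seen_order(self):
        dist = np.full((4, 4), 2.0)
        np.fill_diagonal(dist, 0.0)
        dist[1, 3] = dist[3, 1] = 0.01
        labels = cut_hierarchy(dist, alpha=0.5)
        assert labels[0] == 0  # first gene gets cluster 0
        assert labels.tolist() == [0, 1, 2, 1]


class TestCenters:
    def test_singleton_center_is_row(self):
        C = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        centers = compute_centers(np.array([0, 1]), C)
        assert_allclose(centers, C)

    def test_opposite_rows_cancel(self):
        r = np.array([1.0, -2.0, 3.0])
        centers = compute_centers(np.array([0, 0]), np.vstack([r, -r]))
        assert_allclose(centers[0], 0.0)

    def test_three_rows_hand_mean(self):
        C = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 12.0]])
        centers = compute_centers(np.zeros(3, dtype=int), C)
        assert_allclose(centers[0], [3.0, 6.0])


class TestMergeStep:
    def _state(self, labels, C):
        labels = np.asarray(labels)
        return ClusterState(labels=labels, centers=compute_centers(labels, C))

    def test_identical_centers_merge(self):
        row = np.array([1.0, 2.0, 3.0, 4.0])
        C = np.vstack([row, row, row, row])
        state = self._state([0, 0, 1, 1], C)
        out = merge_step(state, alpha=0.5, C=C)
        assert len(set(out.labels)) == 1

    def test_uncorrelated_centers_unchanged(self):
        C = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
        ])
        state = self._state([0, 1], C)
        out = merge_step(state, alpha=0.5, C=C)
        assert np.array_equal(out.labels, state.labels)

    def test_exactly_correlated_pair_merges(self):
        # centers 0 and 1 share ranks (rho=1); center 2 is reversed
        C = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [10.0, 20.0, 30.0, 40.0],
            [4.0, 3.0, 2.0, 1.0],
        ])
        state = self._state([0, 1, 2], C)
        out = merge_step(state, alpha=0.5, C=C)
        assert partitions_equal(out.labels, [0, 0, 1])

    def test_single_cluster_returned_unchanged(self):
        C = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        state = self._state([0, 0], C)
        assert merge_step(state, 0.5, C) is state


class TestPruneStep:
    def _state(self, labels, C):
        labels = np.asarray(labels)
        return ClusterState(labels=labels, centers=compute_centers(labels, C))

    def test_all_satisfy_unchanged(self):
        C = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [1.1, 2.1, 3.1, 4.1],
        ])
        state = self._state([0, 0], C)
        out = prune_step(state, alpha=0.5, C=C)
        assert out.n_pruned == 0
        assert np.array_equal(out.labels, state.labels)

    def test_planted_outlier_split(self):
        # two aligned rows plus one rank-reversed outlier: the outlier's
        # correlation with the center is negative, below any alpha > 0
        C = np.array([
            [1.0, 2.0, 3.0, 4.0, 5.0],
            [1.5, 2.5, 3.5, 4.5, 5.5],
            [5.0, 4.0, 3.0, 2.0, 1.0],
        ])
        state = self._state([0, 0, 0], C)
        out = prune_step(state, alpha=0.5, C=C)
        assert out.n_pruned == 1
        assert partitions_equal(out.labels, [0, 0, 1])

    def test_singleton_never_pruned(self):
        C = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        state = self._state([0, 1], C)
        out = prune_step(state, alpha=0.99, C=C)
        assert np.array_equal(out.labels, state.labels)


class TestIterateToConvergence:
    def test_fixpoint_returned_identically(self):
        C = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [4.0, 3.0, 2.0, 1.0],
        ])
        labels = np.array([0, 1])
        state = ClusterState(labels=labels, centers=compute_centers(labels, C))
        out = iterate_to_convergence(state, alpha=0.5, C=C)
        assert np.array_equal(out.labels, labels)

    def test_between_center_correlations_below_alpha(self, two_group_coeffs):
        C = two_group_coeffs
        dist = spearman_distance(C).dist
        labels = cut_hierarchy(dist, 0.6)
        state = ClusterState(labels=labels, centers=compute_centers(labels, C))
        out = iterate_to_convergence(state, 0.6, C)
        rho_c = _spearman_matrix(out.centers, constant_ok=True)
        off = rho_c[~np.eye(rho_c.shape[0], dtype=bool)]
        assert out.centers.shape[0] == 1 or np.all(off < 0.6)

    def test_planted_outlier_dataset(self):
        # 3 modules x 3 genes + 1 outlier gene -> 4 clusters
        rng = np.random.default_rng(6)
        K = 20
        t = np.linspace(0, 1, K)
        bases = [np.sin(2 * np.pi * t), np.cos(2 * np.pi * t), t**2]
        rows = [b + 0.01 * rng.normal(size=K) for b in bases for _ in range(3)]
        rows.append(np.sin(7 * np.pi * t))  # outlier pattern
        C = np.vstack(rows)
        gd = spearman_distance(C)
        alpha = 0.8
        labels = cut_hierarchy(gd.dist, alpha)
        state = ClusterState(labels=labels, centers=compute_centers(labels, C))
        out = iterate_to_convergence(state, alpha, C)
        truth = [0, 0, 0, 1, 1, 1, 2, 2, 2, 3]
        assert partitions_equal(out.labels, truth)


class TestSilhouette:
    def test_hand_case(self):
        # A,B together, C alone: sil_A = (0.9-0.1)/0.9
        dist = np.array([
            [0.0, 0.1, 0.9],
            [0.1, 0.0, 0.8],
            [0.9, 0.8, 0.0],
        ])
        sil, mean = silhouette_scores(np.array([0, 0, 1]), dist)
        assert_allclose(sil[0], (0.9 - 0.1) / 0.9)
        assert_allclose(sil[1], (0.8 - 0.1) / 0.8)
        assert sil[2] == 0.0  # singleton convention
        assert_allclose(mean, (sil[0] + sil[1]) / 3)

    def test_perfect_separation(self):
        dist = np.full((4, 4), 1.0)
        np.fill_diagonal(dist, 0.0)
        dist[0, 1] = dist[1, 0] = 0.0
        dist[2, 3] = dist[3, 2] = 0.0
        _, mean = silhouette_scores(np.array([0, 0, 1, 1]), dist)
        assert mean == 1.0

    def test_single_cluster_sentinel(self):
        dist = np.zeros((3, 3))
        _, mean = silhouette_scores(np.zeros(3, dtype=int), dist)
        assert mean == -1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_random_partitions(self, seed):
        rng = np.random.default_rng(seed)
        G = 10
        C = rng.normal(size=(G, 8))
        dist = spearman_distance(C).dist
        labels = rng.integers(0, 3, size=G)
        sil, _ = silhouette_scores(labels, dist)
        assert np.all(sil >= -1.0) and np.all(sil <= 1.0)


class TestRunStihc:
    def test_two_group_recovery(self, two_group_coeffs):
        from stmodules.metrics import adjusted_rand_index

        res = run_stihc(two_group_coeffs, U=20)
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_index(res.labels, truth) == 1.0

    def test_all_identical_single_cluster(self):
        C = np.vstack([[1.0, 2.0, 3.0, 4.0]] * 5)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            res = run_stihc(C, U=10)
        assert len(set(res.labels)) == 1

    def test_deterministic_repeat(self, two_group_coeffs):
        r1 = run_stihc(two_group_coeffs, U=15)
        r2 = run_stihc(two_group_coeffs, U=15)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.alpha_opt == r2.alpha_opt
        assert r1.per_alpha == r2.per_alpha

    def test_alpha_opt_maximizes_mean_silhouette(self, two_group_coeffs):
        res = run_stihc(two_group_coeffs, U=12)
        best = max(row["mean_silhouette"] for row in res.per_alpha)
        chosen = [r for r in res.per_alpha if r["alpha"] == res.alpha_opt]
        assert chosen and chosen[0]["mean_silhouette"] == best
        # ties break toward the larger alpha
        tied = [r["alpha"] for r in res.per_alpha
                if r["mean_silhouette"] == best]
        assert res.alpha_opt == max(tied)

    def test_medoid_center_variant(self, two_group_coeffs):
        from stmodules.metrics import adjusted_rand_index

        res = run_stihc(two_group_coeffs, U=15, center="medoid")
        truth = [0] * 10 + [1] * 10
        assert adjusted_rand_index(res.labels, truth) == 1.0

    def test_imbalance_recovery_small_module(self):
        # the differentiating claim: a 2-gene module survives as its own
        # cluster next to 6/16/25-gene modules
        rng = np.random.default_rng(7)
        K = 40
        t = np.linspace(0, 1, K)
        bases = [np.sin(2 * np.pi * t), np.cos(3 * np.pi * t),
                 (t - 0.5) ** 2, np.exp(-8 * (t - 0.3) ** 2)]
        sizes = (6, 2, 16, 25)
        rows, truth = [], []
        for m, (b, s) in enumerate(zip(bases, sizes)):
            for _ in range(s):
                rows.append(b + 0.02 * rng.normal(size=K))
                truth.append(m)
        res = run_stihc(np.vstack(rows), U=20)
        from stmodules.metrics import adjusted_rand_index

        assert adjusted_rand_index(res.labels, truth) == 1.0
        two_gene_cluster = res.labels[np.array(truth) == 1]
        assert len(set(two_gene_cluster)) == 1
        assert np.sum(res.labels == two_gene_cluster[0]) == 2

    def test_rejects_single_gene(self):
        with pytest.raises(ClusterError):
            run_stihc(np.array([[1.0, 2.0, 3.0]]), U=5)
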