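import math

import numpy as np
import pytest

from rgbdfruit.dpc import (SelectionParams, assign_labels, cluster_blocks,
                           coverage_ranking, cutoff_density, delta_separation,
                           double_sort_select, kde_density,
                           pairwise_distances, prune_clusters)
from rgbdfruit.errors import InputError, ParameterError


# ---- independent brute-force oracles (plain Python, no shared code paths)

def kde_oracle(points, sigma, h=1.0):
    n = len(points)
    out = []
    for i in range(n):
        total = 0.0
        for j in range(n):
            dx = (points[i][0] - points[j][0]) / h
            dy = (points[i][1] - points[j][1]) / h
            total += math.exp(-(dx * dx + dy * dy) / (2 * sigma * sigma)) \
                / (2 * math.pi * sigma * sigma)
        out.append(total / (n * h))
    return np.array(out)


def delta_oracle(dist, rho):
    n = len(rho)
    delta = np.empty(n)
    nnh = np.full(n, -1)
    for i in range(n):
        denser = [j for j in range(n)
                  if rho[j] > rho[i] or (rho[j] == rho[i] and j < i)]
        if not denser:
            delta[i] = max(dist[i][j] for j in range(n))
        else:
            best = min(denser, key=lambda j: (dist[i][j], j))
            delta[i] = dist[i][best]
            nnh[i] = best
    return delta, nnh


def cutoff_oracle(dist, d_c):
    n = len(dist)
    return np.array([sum(1 for j in range(n)
                         if j != i and dist[i][j] <= d_c)
                     for i in range(n)], dtype=float)


def coverage_oracle(labels, sizes):
    totals = {}
    for lab, size in zip(labels, sizes):
        totals[lab] = totals.get(lab, 0) + size
    return sorted(totals, key=lambda lab: (-totals[lab], lab))


class TestPairwiseDistances:
    def test_three_four_five(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self, rng):
        pts = rng.normal(size=(30, 2))
        d = pairwise_distances(pts)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            pairwise_distances(np.array([[0.0, np.nan], [1.0, 1.0]]))


class TestKdeDensity:
    def test_single_point_self_term(self):
        rho = kde_density(np.array([[2.0, 3.0]]), sigma=1.0, h=1.0)
        assert rho[0] == pytest.approx(1.0 / (2 * np.pi))

    def test_coincident_points_equal_single_point_density(self):
        pts = np.tile([[1.5, -2.0]], (7, 1))
        rho = kde_density(pts, sigma=1.0, h=1.0)
        np.testing.assert_allclose(rho, 1.0 / (2 * np.pi))

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(-50, 50, size=(200, 2))
        rho = kde_density(pts, sigma=7.0)
        np.testing.assert_allclose(rho, kde_oracle(pts, 7.0), rtol=1e-12)

    def test_permutation_equivariance(self, rng):
        pts = rng.normal(size=(40, 2)) * 10
        perm = rng.permutation(40)
        np.testing.assert_allclose(kde_density(pts, 3.0)[perm],
                                   kde_density(pts[perm], 3.0), rtol=1e-10)

    @pytest.mark.parametrize("sigma,h", [(0.0, 1.0), (1.0, 0.0), (-1, 1)])
    def test_bad_bandwidth_rejected(self, sigma, h):
        with pytest.raises(ParameterError):
            kde_density(np.zeros((3, 2)), sigma=sigma, h=h)


class TestCutoffDensity:
    def test_collinear_counts(self):
        pts = np.array([[0.0, 0], [1.0, 0], [2.0, 0], [10.0, 0]])
        rho = cutoff_density(pairwise_distances(pts), d_c=1.5)
        assert rho.tolist() == [1, 2, 1, 0]

    def test_d_c_below_min_distance_gives_zero(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        dist = pairwise_distances(pts)
        rho = cutoff_density(dist, d_c=0.5 * dist[dist > 0].min())
        assert rho.max() == 0

    def test_d_c_above_max_distance_counts_everyone(self, rng):
        pts = rng.uniform(0, 10, size=(15, 2))
        dist = pairwise_distances(pts)
        rho = cutoff_density(dist, d_c=dist.max())
        np.testing.assert_array_equal(rho, 14)


class TestDeltaSeparation:
    def test_global_maximum_gets_max_distance(self, rng):
        pts = rng.normal(size=(25, 2))
        dist = pairwise_distances(pts)
        rho = kde_density(pts, 1.0)
        delta, nnh = delta_separation(dist, rho)
        top = int(np.argmax(rho))
        assert delta[top] == pytest.approx(dist[top].max())
        assert nnh[top] == -1

    def test_two_points(self):
        dist = np.array([[0.0, 4.0], [4.0, 0.0]])
        delta, nnh = delta_separation(dist, np.array([2.0, 1.0]))
        assert delta[0] == delta[1] == 4.0
        assert nnh[0] == -1 and nnh[1] == 0

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 20, size=(300, 2))
        dist = pairwise_distances(pts)
        rho = kde_density(pts, 2.0)
        delta, nnh = delta_separation(dist, rho)
        delta_o, nnh_o = delta_oracle(dist, rho)
        np.testing.assert_array_equal(delta, delta_o)
        np.testing.assert_array_equal(nnh, nnh_o)

    def test_ties_broken_by_index(self):
        # all densities equal: point 0 is "densest"; others link to a
        # lower-indexed point
        pts = np.array([[0.0, 0], [1.0, 0], [2.0, 0]])
        delta, nnh = delta_separation(pairwise_distances(pts),
                                      np.ones(3))
        assert nnh.tolist() == [-1, 0, 1]
        assert delta[0] == 2.0


class TestDoubleSortSelect:
    def test_hand_worked_example(self):
        rho = np.array([9.0, 8, 7, 2, 1])
        delta = np.array([1.0, 5, 9, 9, 9])
        centers = double_sort_select(
            rho, delta, SelectionParams(n_density_top=3, n_delta_top=2,
                                        n_keep_clusters=2))
        assert set(centers.tolist()) == {1, 2}
        assert centers[0] == 2  # ordered by descending delta

    def test_equal_rho_reduces_to_delta_sort_on_low_indices(self):
        rho = np.ones(10)
        delta = np.arange(10, dtype=float)
        centers = double_sort_select(
            rho, delta, SelectionParams(n_density_top=6, n_delta_top=3,
                                        n_keep_clusters=3))
        # density ties keep indices 0..5; top deltas among them: 5, 4, 3
        assert centers.tolist() == [5, 4, 3]

    def test_centers_distinct_and_sized(self, rng):
        rho = rng.uniform(size=50)
        delta = rng.uniform(size=50)
        params = SelectionParams(n_density_top=20, n_delta_top=15,
                                 n_keep_clusters=3)
        centers = double_sort_select(rho, delta, params)
        assert len(centers) == 15
        assert len(set(centers.tolist())) == 15

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError, match="n_density_top"):
            double_sort_select(np.ones(5), np.ones(5), SelectionParams())


class TestAssignLabels:
    def test_two_blobs_recovered(self, rng):
        blob1 = rng.normal(0, 1, size=(50, 2))
        blob2 = rng.normal(0, 1, size=(50, 2)) + np.array([30.0, 0.0])
        pts = np.vstack([blob1, blob2])
        dist = pairwise_distances(pts)
        rho = kde_density(pts, 1.0)
        delta, nnh = delta_separation(dist, rho)
        peaks = [int(np.argmax(rho[:50])), 50 + int(np.argmax(rho[50:]))]
        labels = assign_labels(nnh, rho, np.array(peaks), dist=dist)
        # oracle: nearest blob mean
        truth = (np.linalg.norm(pts - blob1.mean(0), axis=1)
                 > np.linalg.norm(pts - blob2.mean(0), axis=1)).astype(int)
        assert (labels == truth).all()

    def test_all_points_centers(self):
        rho = np.array([3.0, 2, 1])
        nnh = np.array([-1, 0, 1])
        labels = assign_labels(nnh, rho, np.array([0, 1, 2]))
        assert labels.tolist() == [0, 1, 2]

    def test_single_center_takes_all(self, rng):
        pts = rng.normal(size=(30, 2))
        dist = pairwise_distances(pts)
        rho = kde_density(pts, 1.0)
        delta, nnh = delta_separation(dist, rho)
        labels = assign_labels(nnh, rho, np.array([int(np.argmax(rho))]))
        assert (labels == 0).all()


class TestPruneClusters:
    def test_three_clusters_unchanged(self):
        labels = np.array([0, 0, 1, 1, 2, 2])
        sizes = np.array([10, 10, 8, 8, 5, 5])
        out = prune_clusters(labels, sizes, 3)
        np.testing.assert_array_equal(out, labels)

    def test_tiny_clusters_pruned_to_three(self, rng):
        # 3 big feature blobs + 12 singleton outliers
        big = [rng.normal(size=(30, 2)) + offset
               for offset in ([0, 0], [40, 0], [0, 40])]
        tiny = rng.uniform(100, 200, size=(12, 2))
        pts = np.vstack([*big, tiny])
        sizes = np.full(len(pts), 100)
        sizes[-12:] = 3  # tiny pixel coverage
        dist = pairwise_distances(pts)
        rho = kde_density(pts, 2.0)
        delta, nnh = delta_separation(dist, rho)
        centers = np.concatenate([
            [int(np.argmax(rho[i * 30:(i + 1) * 30])) + i * 30
         for i in range(3)], np.arange(90, 102)])
        labels = assign_labels(nnh, rho, centers, dist=dist)
        pruned = prune_clusters(labels, sizes, 3, nn_higher=nnh, dist=dist)
        assert len(np.unique(pruned)) == 3
        # the three surviving labels are those of the big blobs
        assert set(np.unique(pruned)) == {0, 1, 2}

    def test_coverage_ranking_matches_brute_force(self, rng):
        labels = rng.integers(0, 8, size=100)
        sizes = rng.integers(1, 500, size=100)
        ranking = coverage_ranking(labels, sizes)
        assert ranking.tolist() == coverage_oracle(labels.tolist(),
                                                   sizes.tolist())

    def test_fewer_clusters_than_keep_warns(self):
        labels = np.array([0, 0, 1])
        with pytest.warns(UserWarning):
            out = prune_clusters(labels, np.array([5, 5, 5]), 3)
        np.testing.assert_array_equal(out, labels)


class TestClusterBlocks:
    def test_deterministic(self, rng):
        pts = rng.normal(size=(60, 2)) * 5
        sizes = rng.integers(50, 400, size=60)
        s1 = cluster_blocks(pts, sizes)
        s2 = cluster_blocks(pts, sizes)
        np.testing.assert_array_equal(s1.labels, s2.labels)
        np.testing.assert_array_equal(s1.centers, s2.centers)

    def test_three_blob_cloud_high_agreement(self, rng):
        """Fruit/leaf/branch-like blobs should be recovered nearly exactly."""
        from sklearn.metrics import adjusted_rand_score
        blobs = [rng.normal(0, 1.5, size=(60, 2)) + offset
                 for offset in ([35, 70], [14, 49], [30, 25])]
        pts = np.vstack(blobs)
        truth = np.repeat([0, 1, 2], 60)
        sizes = np.full(len(pts), 300)
        # a three-mode cloud warrants keeping three clusters
        state = cluster_blocks(
            pts, sizes, params=SelectionParams(60, 4, 3))
        assert adjusted_rand_score(truth, state.labels) >= 0.95
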