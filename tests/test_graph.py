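"""Graph variant: distances, Hamiltonian path heuristic, edge counts, limits."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from wcusum import GraphCUSUM, InvalidInputError, WeightScheme, distance_matrix, shp_order
from wcusum.graph import (
    EdgeCountCurve,
    PathOrder,
    edge_count_curve,
    graph_limit_quantiles,
    graph_wc_statistic,
    normalize_graph_statistic,
    permutation_edge_moments,
)

MC_SMALL = dict(seed=99, grid=500, reps=20_000)


class TestDistances:
    def test_identical_rows_and_symmetry(self, rng):
        X = rng.standard_normal((6, 3))
        X[4] = X[1]
        d = distance_matrix(X, "euclidean").values
        assert d[1, 4] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0) and np.all(d >= 0)

    def test_one_dimensional_reduction(self, rng):
        y = rng.standard_normal(8)
        de = distance_matrix(y[:, None], "euclidean").values
        dp = distance_matrix(y[:, None], "pseudo").values
        expected = np.abs(y[:, None] - y[None, :])
        assert np.allclose(de, expected, atol=1e-10)
        assert np.allclose(dp, expected, atol=1e-12)

    def test_unknown_metric(self):
        with pytest.raises(InvalidInputError):
            distance_matrix(np.eye(4), "manhattan")


class TestSHP:
    def test_collinear_points_sorted(self):
        pos = np.array([5.0, 1.0, 3.0, 2.0, 4.0])
        path = shp_order(distance_matrix(pos[:, None], "euclidean"))
        visited = pos[path.order]
        assert np.array_equal(visited, np.sort(pos)) or np.array_equal(visited, np.sort(pos)[::-1])

    def test_three_nodes_optimal(self, rng):
        X = rng.standard_normal((3, 2))
        dist = distance_matrix(X, "euclidean")
        D = dist.values
        best = min(
            (D[p[0], p[1]] + D[p[1], p[2]] for p in itertools.permutations(range(3))),
        )
        assert shp_order(dist).length == pytest.approx(best, rel=1e-12)

    def test_beats_identity_order(self, rng):
        for _ in range(100):
            X = rng.standard_normal((12, 2))
            dist = distance_matrix(X, "euclidean")
            naive = float(dist.values[np.arange(11), np.arange(1, 12)].sum())
            assert shp_order(dist).length <= naive + 1e-12

    def test_deterministic(self, rng):
        X = rng.standard_normal((15, 4))
        d = distance_matrix(X, "euclidean")
        assert np.array_equal(shp_order(d).order, shp_order(d).order)


class TestEdgeCounts:
    def test_identity_path_single_crossing(self):
        path = PathOrder(order=np.arange(9), length=0.0)
        curve = edge_count_curve(path)
        assert np.all(curve.counts == 1.0)

    def test_permutation_mean_formula(self):
        mean, _ = permutation_edge_moments(10, 5)
        assert mean == 5.0

    def test_exhaustive_permutation_moments_n6(self):
        """Mean/variance over all 720 node orders match the closed forms."""
        n = 6
        counts = np.array([
            edge_count_curve(PathOrder(order=np.array(p), length=0.0)).counts
            for p in itertools.permutations(range(n))
        ])
        k = np.arange(1, n)
        mean, var = permutation_edge_moments(n, k)
        assert np.allclose(counts.mean(axis=0), mean, atol=1e-12)
        assert np.allclose(counts.var(axis=0), var, atol=1e-12)


class TestGraphStatistic:
    def test_zero_at_permutation_mean(self):
        n = 8
        mean, _ = permutation_edge_moments(n, np.arange(1, n))
        curve = EdgeCountCurve(counts=mean, n=n)
        for gamma in (1, 2):
            assert graph_wc_statistic(curve, WeightScheme(n, "center", gamma)) == 0.0

    def test_hand_value_identity_path_n4(self):
        path = PathOrder(order=np.arange(4), length=0.0)
        curve = edge_count_curve(path)
        # center weights (3,4,3); deviations mean-1 = (0.5, 1.0, 0.5)
        expected = 0.25 / 3 + 1.0 / 4 + 0.25 / 3
        got = graph_wc_statistic(curve, WeightScheme(4, "center", 2))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_reversal_invariance(self, rng):
        X = rng.standard_normal((10, 3))
        path = shp_order(distance_matrix(X, "euclidean"))
        rev = PathOrder(order=path.order[::-1].copy(), length=path.length)
        c1, c2 = edge_count_curve(path), edge_count_curve(rev)
        assert np.array_equal(c1.counts, c2.counts)

    def test_unsupported_gamma(self):
        curve = edge_count_curve(PathOrder(order=np.arange(5), length=0.0))
        with pytest.raises(InvalidInputError):
            graph_wc_statistic(curve, WeightScheme(5, "center", 3))


class TestLimits:
    def test_gamma1_expectation_identity(self):
        """E of the gamma=1 limit is 0: the additive constant cancels the
        spectral mass (1 for center, 1 - log 2 for left/right)."""
        from wcusum.bridge import graph_limit_samples

        for tau in ("center", "left"):
            sample = graph_limit_samples(tau, 1, **MC_SMALL)
            assert abs(sample.mean()) < 0.05

    def test_quantiles_increase_in_p(self):
        qs = [graph_limit_quantiles("center", 2, p, **MC_SMALL) for p in (0.5, 0.9, 0.99)]
        assert qs[0] < qs[1] < qs[2]

    def test_centred_count_scaling_at_midpoint(self, rng):
        """The sqrt(2n)-scaled centred cross-count at k=n/2 has mean 0 and
        the variance 2 t^2 (1-t)^2 shared by the bridge-squared limit, and
        is asymptotically normal under the exact permutation null (the
        combinatorial CLT); see the module docstring on why the normal
        shape, not the bridge-squared shape, is the true null."""
        n = 400
        k = n // 2
        vals = np.empty(3000)
        for i in range(vals.size):
            perm = rng.permutation(n)
            curve = edge_count_curve(PathOrder(order=perm, length=0.0))
            vals[i] = (curve.perm_mean[k - 1] - curve.counts[k - 1]) / np.sqrt(2 * n)
        t = 0.5
        target_var = 2 * t**2 * (1 - t) ** 2
        assert vals.mean() == pytest.approx(0.0, abs=4 * np.sqrt(target_var / vals.size))
        assert vals.var() == pytest.approx(target_var, rel=0.15)
        # normality of the standardized counts (lattice-adjusted KS)
        z = (vals - vals.mean()) / vals.std()
        z.sort()
        grid = np.linspace(-3, 3, 200)
        ecdf = np.searchsorted(z, grid, side="right") / z.size
        assert np.max(np.abs(ecdf - sps.norm.cdf(grid))) < 0.06


class TestGraphTest:
    def test_null_calibration_default(self, rng):
        """i.i.d. rows, exact permutation calibration: rejection at the
        nominal level."""
        from wcusum.bridge import mc_quantile
        from wcusum.graph import (
            distance_matrix as dm,
            graph_wc_statistic as gws,
            normalize_graph_statistic as ngs,
            permutation_null_sample,
        )

        n, reps = 100, 1000
        crit = mc_quantile(permutation_null_sample(n, "center", 2, reps=5000), 0.95)
        rej = 0
        for _ in range(reps):
            X = rng.standard_normal((n, 5))
            curve = edge_count_curve(shp_order(dm(X, "euclidean")))
            rej += ngs(gws(curve, WeightScheme(n, "center", 2)), n, 2) > crit
        assert rej / reps == pytest.approx(0.05, abs=0.03)

    def test_asymptotic_calibration_gamma1_near_level_gamma2_conservative(self, rng):
        """Brownian-limit calibration: for gamma=1 the limit's first two
        moments match the permutation null, giving rejection close to the
        level; for gamma=2 the heavier-tailed limit is conservative."""
        from wcusum.graph import distance_matrix as dm

        reps, n = 400, 100
        rej = {1: 0, 2: 0}
        for _ in range(reps):
            X = rng.standard_normal((n, 5))
            d = dm(X, "euclidean")
            for gamma in (1, 2):
                res = GraphCUSUM(dist=d, tau_kind="center", gamma=gamma).fit(
                    level=0.05, calibration="asymptotic", **MC_SMALL)
                rej[gamma] += res.reject
        assert 0.05 - 0.035 <= rej[1] / reps <= 0.05 + 0.035
        assert rej[2] / reps < 0.05

    def test_permutation_calibration_per_fit(self, rng):
        X = rng.standard_normal((40, 5))
        res = GraphCUSUM(X, tau_kind="center", gamma=2).fit(
            level=0.05, calibration="permutation", perm_reps=300, perm_seed=3)
        assert 0.0 <= res.p_value <= 1.0
        assert res.calibration == "permutation"

    def test_variance_change_euclidean_vs_pseudo(self, rng):
        """A pure variance change is visible to the euclidean metric but
        not to the row-mean pseudo-metric."""
        reps, n, q = 100, 60, 30
        rej_e = rej_p = 0
        for _ in range(reps):
            X = rng.standard_normal((n, q))
            X[n // 2:] *= np.sqrt(3.0)
            rej_e += GraphCUSUM(X, metric_kind="euclidean", gamma=2).fit(perm_reps=500).reject
            rej_p += GraphCUSUM(X, metric_kind="pseudo", gamma=2).fit(perm_reps=500).reject
        assert rej_e / reps > rej_p / reps + 0.2
        assert rej_p / reps < 0.2

    def test_detects_mean_shift_and_estimates_location(self, rng):
        X = rng.standard_normal((60, 40))
        X[30:] += 1.0
        res = GraphCUSUM(X, metric_kind="pseudo", gamma=2).fit()
        assert res.reject
        assert abs(res.changepoint - 30) <= 3
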