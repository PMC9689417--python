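"""Model classes: weighted CUSUM, Poisson variant, self-normalized variant."""

import numpy as np
import pytest

from wcusum import (
    DegenerateDataError,
    InvalidInputError,
    PoissonWeightedCUSUM,
    SelfNormalizedCUSUM,
    WeightedCUSUM,
    WeightScheme,
    null_distribution,
    wc_statistic,
)
from wcusum.simulate import SimConfig, gen_poisson_mixed
from wcusum.stats import variance_estimate


class TestWeightedCUSUM:
    def test_single_column_matches_vector_formulas(self, rng, tau_kind):
        y = rng.standard_normal(25)
        res = WeightedCUSUM(y[:, None], tau_kind=tau_kind).fit()
        expected = wc_statistic(y, WeightScheme(25, tau_kind)) / variance_estimate(y)
        assert res.statistic == pytest.approx(expected, rel=1e-12)
        assert res.n == 25 and res.q == 1

    def test_result_consistency(self, rng):
        y = rng.standard_normal((40, 10))
        y[25:] += 0.5
        res = WeightedCUSUM(y, tau_kind="left").fit(level=0.05)
        assert res.statistic >= 0
        assert 0.0 <= res.p_value <= 1.0
        assert res.reject == (res.statistic > res.critical_value)
        assert res.reject == (res.p_value < res.level)
        assert 1 <= res.changepoint <= 39

    def test_calibrated_against_exact_finite_n_spectrum(self, rng):
        y = rng.standard_normal((20, 4))
        res = WeightedCUSUM(y, tau_kind="center").fit(level=0.05)
        dist = null_distribution(20, "center")
        assert res.critical_value == pytest.approx(dist.quantile(0.95), abs=1e-9)
        assert res.p_value == pytest.approx(dist.pvalue(res.statistic), abs=1e-9)

    def test_known_sigma2_mode(self, rng):
        y = rng.standard_normal(30)
        res = WeightedCUSUM(y, tau_kind="center", sigma2=1.0).fit()
        assert res.variance_estimate == 1.0
        assert res.statistic == pytest.approx(wc_statistic(y, WeightScheme(30, "center")))

    def test_studentized_statistic_scale_invariant(self, rng):
        y = rng.standard_normal((30, 3))
        s1 = WeightedCUSUM(y, tau_kind="right").fit().statistic
        s2 = WeightedCUSUM(5.0 * y, tau_kind="right").fit().statistic
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_constant_data_raises(self):
        with pytest.raises(DegenerateDataError):
            WeightedCUSUM(np.ones((10, 3))).fit()

    def test_summary_mentions_key_quantities(self, rng):
        res = WeightedCUSUM(rng.standard_normal((12, 2))).fit()
        text = res.summary()
        for token in ("statistic", "p-value", "changepoint", "tau_kind"):
            assert token in text

    def test_plot_profile(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        res = WeightedCUSUM(rng.standard_normal((15, 2))).fit()
        ax = res.plot()
        assert ax.get_xlabel() == "split k"


class TestPoissonVariant:
    def test_zero_row_mean_named_in_error(self):
        counts = np.ones((6, 2))
        counts[3] = 0.0
        with pytest.raises(InvalidInputError, match=r"\b4\b"):
            PoissonWeightedCUSUM(counts)

    def test_identical_counts_give_zero_statistic(self):
        counts = np.full((8, 3), 4.0)
        log_rm = np.log(counts.mean(axis=1))
        assert wc_statistic(log_rm, WeightScheme(8, "center")) == 0.0
        with pytest.raises(DegenerateDataError):
            PoissonWeightedCUSUM(counts).fit()

    def test_null_calibration_mixed_model(self):
        """No rate change: rejection close to the nominal level."""
        from wcusum.quadform import null_critical_value

        cfg = SimConfig(n=40, q=100, k_star=20, model="poisson_mixed",
                        nu2=0.1, rho_minus=0.5, rho_plus=0.5, seed=11)
        crit = null_critical_value(40, "center", 0.95)
        scheme = WeightScheme(40, "center")
        rej = 0
        reps = 2000
        for r in range(reps):
            rng = np.random.default_rng(np.random.SeedSequence(11, spawn_key=(r,)))
            y = np.log(gen_poisson_mixed(cfg, rng).row_means)
            rej += wc_statistic(y, scheme) / variance_estimate(y) > crit
        assert rej / reps == pytest.approx(0.05, abs=0.02)

    def test_power_under_rate_change(self):
        """Rate step rho 0 -> 0.5 at midpoint: essentially always detected."""
        cfg = SimConfig(n=40, q=100, k_star=20, model="poisson_mixed",
                        nu2=0.1, rho_minus=0.0, rho_plus=0.5, seed=5)
        rej = 0
        for r in range(50):
            rng = np.random.default_rng(np.random.SeedSequence(5, spawn_key=(r,)))
            data = gen_poisson_mixed(cfg, rng)
            res = PoissonWeightedCUSUM(data, tau_kind="center").fit()
            rej += res.reject
        assert rej / 50 > 0.9
        assert abs(res.changepoint - 20) <= 3


class TestSelfNormalized:
    def test_results_scale_invariant(self, rng):
        y = rng.standard_normal(50)
        r1 = SelfNormalizedCUSUM(y).fit()
        r2 = SelfNormalizedCUSUM(-4.0 * y + 2.0).fit()
        assert r1.sum_statistic == pytest.approx(r2.sum_statistic, rel=1e-9)
        assert r1.max_statistic == pytest.approx(r2.max_statistic, rel=1e-9)

    def test_null_calibration_under_ar1(self):
        """AR(1) dependence (phi=0.3): type-I error near nominal 0.05."""
        from scipy.signal import lfilter

        phi, n, reps = 0.3, 200, 2000
        rng = np.random.default_rng(404)
        eps = rng.standard_normal((reps, n))
        eps[:, 0] /= np.sqrt(1 - phi**2)
        Y = lfilter([1.0], [1.0, -phi], eps, axis=1)
        model0 = SelfNormalizedCUSUM(Y[0])  # warm the MC limit table
        crit_sum = model0.fit().sum_critical_value
        from wcusum.stats import selfnorm_statistics

        rej_sum = sum(selfnorm_statistics(row)[0] > crit_sum for row in Y)
        assert rej_sum / reps == pytest.approx(0.05, abs=0.02)

    def test_power_with_mean_shift(self):
        from wcusum.stats import selfnorm_statistics
        from wcusum import SelfNormalizedCUSUM as SNC

        n, reps = 200, 100
        rng = np.random.default_rng(17)
        crit = SNC(rng.standard_normal(n)).fit().sum_critical_value
        rej = 0
        for _ in range(reps):
            y = rng.standard_normal(n)
            y[n // 2:] += 1.0
            rej += selfnorm_statistics(y)[0] > crit
        assert rej / reps > 0.9

    def test_pvalues_and_rejections_consistent(self, rng):
        y = rng.standard_normal(60)
        y[40:] += 2.0
        res = SelfNormalizedCUSUM(y).fit(level=0.05)
        assert res.reject_sum == (res.sum_statistic > res.sum_critical_value)
        assert res.reject_max == (res.max_statistic > res.max_critical_value)
        assert "Self-normalized" in res.summary()
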