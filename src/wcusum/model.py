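"""Model classes for weighted CUSUM change-point testing.

The public surface follows the statsmodels idiom: a model object is
built from data plus configuration, ``fit()`` performs the test and
returns a results object carrying the statistic, its calibration
(p-value and critical value), the change-point estimate and a
``summary()`` table.

* :class:`WeightedCUSUM` — the standardized quadratic-weight test for a
  mean change in (row means of) approximately normal data, calibrated
  by the exact finite-n weighted chi-square null distribution.
* :class:`PoissonWeightedCUSUM` — the same test applied to the log row
  means of count data, the transform delivered by the saddle-point
  approximation to the Poisson mixed-model marginal likelihood.
* :class:`SelfNormalizedCUSUM` — scale-free sum and max statistics with
  data-driven random norming, valid under weak temporal dependence and
  calibrated against Monte-Carlo samples of their Brownian-bridge
  limits.

The graph-based variant lives in :mod:`wcusum.graph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bridge, quadform, stats
from .errors import DegenerateDataError, InvalidInputError
from .series import SeriesData, as_series_data
from .weights import WeightScheme

__all__ = [
    "WeightedCUSUM",
    "PoissonWeightedCUSUM",
    "SelfNormalizedCUSUM",
    "CUSUMTestResults",
    "SelfNormResults",
]


def _summary_table(title: str, rows: list[tuple[str, object]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * 46]
    for k, v in rows:
        if isinstance(v, float):
            v = f"{v:.6g}"
        lines.append(f"{k:<{width}}{v}")
    lines.append("=" * 46)
    return "\n".join(lines)


@dataclass(frozen=True)
class CUSUMTestResults:
    """Outcome of a weighted CUSUM test.

    ``statistic`` is the standardized value compared against the
    weighted chi-square null; ``changepoint`` is the 1-based index k̂ of
    the last pre-change observation.
    """

    statistic: float
    raw_statistic: float
    variance_estimate: float
    p_value: float
    critical_value: float
    level: float
    changepoint: int
    n: int
    q: int
    tau_kind: str
    gamma: float
    variant: str = "wc"
    degenerate_changepoint: bool = False
    model: object = field(default=None, repr=False, compare=False)

    @property
    def reject(self) -> bool:
        return self.statistic > self.critical_value

    def summary(self) -> str:
        rows = [
            ("variant", self.variant),
            ("n (time points)", self.n),
            ("q (replicates)", self.q),
            ("tau_kind", self.tau_kind),
            ("gamma", self.gamma),
            ("statistic", self.statistic),
            ("variance estimate", self.variance_estimate),
            (f"critical value ({1 - self.level:.3g})", self.critical_value),
            ("p-value", self.p_value),
            ("reject H0", str(self.reject)),
            ("changepoint estimate", self.changepoint),
        ]
        return _summary_table("Weighted CUSUM change-point test", rows)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "raw_statistic": self.raw_statistic,
            "variance_estimate": self.variance_estimate,
            "p_value": self.p_value,
            "critical_value": self.critical_value,
            "level": self.level,
            "k_hat": self.changepoint,
            "n": self.n,
            "q": self.q,
            "tau": self.tau_kind,
            "gamma": self.gamma,
            "variant": self.variant,
        }

    def plot(self, ax=None):
        """Plot the weighted CUSUM profile with the estimated change point."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.model._test_series() if self.model is not None else None
        if y is None:
            raise InvalidInputError("results were created without a model; nothing to plot")
        scheme = WeightScheme(self.n, self.tau_kind, 2.0)
        ps = np.cumsum(y - y.mean())[:-1]
        profile = np.abs(ps) / np.sqrt(scheme.weights())
        ax.plot(np.arange(1, self.n), profile, lw=1.5)
        ax.axvline(self.changepoint, color="crimson", ls="--", label=f"k̂ = {self.changepoint}")
        ax.set_xlabel("split k")
        ax.set_ylabel(r"$w_k^{-1/2}\,|S_k|$")
        ax.legend()
        return ax


class WeightedCUSUM:
    """Weighted CUSUM test for a single mean change.

    Parameters
    ----------
    data : array-like, DataFrame or SeriesData
        n x q matrix, rows = time.  The test operates on the row means.
    tau_kind : {"left", "center", "right"}
        Prior change location: "left" (tau=0) is most sensitive to late
        changes, "right" (tau=n) to early changes.
    gamma : float
        Exponent on the partial sums; the exact null calibration
        requires the default quadratic case.
    sigma2 : float, optional
        Known variance of the row means.  When omitted, the plug-in
        estimator (n-1)^{-1} sum (Ybar_i - mu)^2 studentizes the
        statistic, which leaves the exact null valid asymptotically.
    """

    variant = "wc"

    def __init__(self, data, tau_kind: str = "center", gamma: float = 2.0,
                 sigma2: float | None = None):
        self.data = as_series_data(data)
        if self.data.n < 3:
            raise InvalidInputError("testing requires at least 3 time points")
        self.scheme = WeightScheme(self.data.n, tau_kind, gamma)
        if sigma2 is not None and sigma2 <= 0:
            raise InvalidInputError("a known sigma2 must be positive")
        self.sigma2 = sigma2

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, transpose: bool = False, **kwargs) -> "WeightedCUSUM":
        return cls(SeriesData.from_dataframe(df, transpose=transpose), **kwargs)

    def _test_series(self) -> np.ndarray:
        return self.data.row_means

    def fit(self, level: float = 0.05) -> CUSUMTestResults:
        if not 0.0 < level < 1.0:
            raise InvalidInputError(f"level must lie in (0, 1), got {level}")
        y = self._test_series()
        raw = stats.wc_statistic(y, self.scheme)
        s2 = self.sigma2 if self.sigma2 is not None else stats.variance_estimate(y)
        statistic = raw / s2
        if self.scheme.gamma != 2:
            raise InvalidInputError(
                "exact null calibration is available only for gamma=2; "
                "use gamma=2 or calibrate by simulation"
            )
        # exact finite-n spectrum, not the series limit
        dist = quadform.null_distribution(self.scheme.n, self.scheme.tau_kind)
        p = dist.pvalue(statistic)
        crit = quadform.null_critical_value(self.scheme.n, self.scheme.tau_kind, 1.0 - level)
        degenerate = bool(np.ptp(y) <= 1e-14 * max(1.0, float(np.abs(y).max())))
        khat = stats.estimate_changepoint(y, self.scheme)
        return CUSUMTestResults(
            statistic=statistic, raw_statistic=raw, variance_estimate=s2,
            p_value=p, critical_value=crit, level=level, changepoint=khat,
            n=self.data.n, q=self.data.q, tau_kind=self.scheme.tau_kind,
            gamma=self.scheme.gamma, variant=self.variant,
            degenerate_changepoint=degenerate, model=self,
        )


class PoissonWeightedCUSUM(WeightedCUSUM):
    """Weighted CUSUM test for a rate change in Poisson mixed-model counts.

    The saddle-point approximation to the marginal likelihood of counts
    with conditional mean exp(rho_i + U_i) reduces the likelihood-ratio
    statistic to the weighted CUSUM of the *log row means*, so the test
    transforms the counts and reuses the normal-case null spectrum.
    Rows with zero mean count are rejected explicitly — no continuity
    correction is applied silently.
    """

    variant = "poisson"

    def __init__(self, counts, tau_kind: str = "center", gamma: float = 2.0):
        data = as_series_data(counts)
        if np.any(data.values < 0):
            raise InvalidInputError("counts must be nonnegative")
        rm = data.row_means
        zero_rows = np.flatnonzero(rm <= 0)
        if zero_rows.size:
            raise InvalidInputError(
                "log transform undefined: zero row mean(s) at time index(es) "
                f"{(zero_rows + 1).tolist()}"
            )
        super().__init__(data, tau_kind=tau_kind, gamma=gamma)

    def _test_series(self) -> np.ndarray:
        return np.log(self.data.row_means)


@dataclass(frozen=True)
class SelfNormResults:
    """Self-normalized sum (S) and max (M) statistics with MC p-values."""

    sum_statistic: float
    max_statistic: float
    sum_p_value: float
    max_p_value: float
    sum_critical_value: float
    max_critical_value: float
    level: float
    changepoint: int
    n: int
    q: int

    @property
    def reject_sum(self) -> bool:
        return self.sum_statistic > self.sum_critical_value

    @property
    def reject_max(self) -> bool:
        return self.max_statistic > self.max_critical_value

    def summary(self) -> str:
        rows = [
            ("n (time points)", self.n),
            ("q (replicates)", self.q),
            ("sum statistic S", self.sum_statistic),
            ("S p-value", self.sum_p_value),
            (f"S critical value ({1 - self.level:.3g})", self.sum_critical_value),
            ("max statistic M", self.max_statistic),
            ("M p-value", self.max_p_value),
            (f"M critical value ({1 - self.level:.3g})", self.max_critical_value),
            ("changepoint estimate", self.changepoint),
        ]
        return _summary_table("Self-normalized CUSUM change-point test", rows)

    def to_dict(self) -> dict:
        return {
            "statistic": self.sum_statistic,
            "max_statistic": self.max_statistic,
            "p_value": self.sum_p_value,
            "max_p_value": self.max_p_value,
            "critical_value": self.sum_critical_value,
            "max_critical_value": self.max_critical_value,
            "level": self.level,
            "k_hat": self.changepoint,
            "n": self.n,
            "q": self.q,
            "variant": "selfnorm",
        }


class SelfNormalizedCUSUM:
    """Self-normalized change-point test for weakly dependent series.

    Replaces the long-run variance with the random within-segment
    norming of Shao and Zhang, making both the summed and the max
    statistic exactly scale- and location-invariant with pivotal
    Brownian-bridge limits under mixing/linear-process dependence.
    Calibration uses Monte-Carlo samples of the limit functionals
    (fixed documented seed; see :mod:`wcusum.bridge`).
    """

    def __init__(self, data, mc_seed: int = bridge.DEFAULT_SEED,
                 mc_grid: int = bridge.DEFAULT_GRID, mc_reps: int = bridge.DEFAULT_REPS):
        self.data = as_series_data(data)
        if self.data.n < 4:
            raise InvalidInputError("self-normalized testing requires n >= 4")
        self._mc_key = (mc_seed, mc_grid, mc_reps)

    def fit(self, level: float = 0.05) -> SelfNormResults:
        if not 0.0 < level < 1.0:
            raise InvalidInputError(f"level must lie in (0, 1), got {level}")
        y = self.data.row_means
        if np.ptp(y) <= 1e-14 * max(1.0, float(np.abs(y).max())):
            raise DegenerateDataError("constant series; self-normalized test undefined")
        s_sum, s_max = stats.selfnorm_statistics(y)
        ref_sum, ref_max = bridge.selfnorm_limit_samples(*self._mc_key)
        khat = stats.estimate_changepoint(y, WeightScheme(self.data.n, "center", 2.0))
        return SelfNormResults(
            sum_statistic=s_sum, max_statistic=s_max,
            sum_p_value=bridge.mc_pvalue(ref_sum, s_sum),
            max_p_value=bridge.mc_pvalue(ref_max, s_max),
            sum_critical_value=bridge.mc_quantile(ref_sum, 1.0 - level),
            max_critical_value=bridge.mc_quantile(ref_max, 1.0 - level),
            level=level, changepoint=khat, n=self.data.n, q=self.data.q,
        )
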