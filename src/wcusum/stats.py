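"""Core weighted-CUSUM statistics and estimators (functional layer).

Everything here operates on plain 1-d numpy arrays (typically the row
means of a SeriesData); the model classes in :mod:`wcusum.model` wrap
these functions with calibration and reporting.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad as _quad

from .errors import DegenerateDataError, InvalidInputError
from .weights import WeightScheme, compute_weights

__all__ = [
    "wc_statistic",
    "variance_estimate",
    "estimate_changepoint",
    "selfnorm_weights",
    "selfnorm_statistics",
    "saddlepoint_integral",
    "log_saddlepoint_integral",
]


def _centered_partial_sums(y: np.ndarray) -> np.ndarray:
    """Partial sums of (Y_i - Ybar), i = 1..n-1."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise InvalidInputError("need a 1-d series of length >= 2")
    return np.cumsum(y - y.mean())[:-1]


def wc_statistic(y: np.ndarray, scheme: WeightScheme) -> float:
    """The weighted CUSUM statistic sum_k w_k^{-1} |S_k|^gamma.

    ``S_k`` is the k-th partial sum of the centred series.  For
    gamma = 2 this equals the quadratic form Y'QY with Q from
    :func:`wcusum.weights.build_Q`.
    """
    ps = _centered_partial_sums(y)
    if ps.size != scheme.n - 1:
        raise InvalidInputError(
            f"series length {ps.size + 1} does not match scheme n={scheme.n}"
        )
    w = compute_weights(scheme)
    return float(np.sum(np.abs(ps) ** scheme.gamma / w))


def variance_estimate(y: np.ndarray) -> float:
    """The plug-in variance (n-1)^{-1} sum (Y_i - Ybar)^2.

    Raises DegenerateDataError on a constant series, where the
    studentized statistic is undefined (0/0).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise InvalidInputError("need at least 2 observations")
    s2 = float(np.var(y, ddof=1))
    if s2 <= 0.0 or np.ptp(y) <= 1e-14 * max(1.0, float(np.abs(y).max())):
        raise DegenerateDataError("series is (numerically) constant; variance estimate is 0")
    return s2


def estimate_changepoint(y: np.ndarray, scheme: WeightScheme) -> int:
    """Change-point estimate: argmax_k w_k^{-1/2} |S_k| (1-based index).

    The absolute value makes the estimator direction-agnostic (the sign
    of the drift depends on the direction of the mean shift); ties are
    broken to the smallest k, so a constant series returns k=1.
    """
    ps = _centered_partial_sums(y)
    w = compute_weights(scheme)
    crit = np.abs(ps) / np.sqrt(w)
    return int(np.argmax(crit)) + 1


# -- self-normalization (weak dependence) ----------------------------------

def selfnorm_weights(y: np.ndarray, k: int) -> float:
    """Self-normalizing random weight w_k at split k (1 <= k <= n-1).

    Forward part: sum over i <= k of {S_i - (i/k) S_k}^2, with S_i the
    i-th partial sum; backward part: sum over i > k of
    {R_i - (n-i+1)/(n-k) R_{k+1}}^2, with R_i the backward partial sum
    from i to n.  These are the within-segment CUSUM sums of squares of
    the two candidate segments, a data-driven norming that removes the
    long-run variance under weak dependence.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if not 1 <= k <= n - 1:
        raise InvalidInputError(f"split k must satisfy 1 <= k <= n-1, got {k}")
    S = np.cumsum(y)
    i_fwd = np.arange(1, k + 1, dtype=float)
    fwd = S[:k] - (i_fwd / k) * S[k - 1]
    R = np.cumsum(y[::-1])[::-1]  # R[i-1] = sum_{j=i}^{n} y_j
    i_back = np.arange(k + 1, n + 1, dtype=float)
    back = R[k:] - ((n - i_back + 1.0) / (n - k)) * R[k]
    return float(np.sum(fwd**2) + np.sum(back**2))


def _selfnorm_weights_all(y: np.ndarray) -> np.ndarray:
    """Vectorised w_k for all k = 1..n-1 in O(n) using prefix sums."""
    y = np.asarray(y, dtype=float)
    n = y.size
    S = np.cumsum(y)
    cS2 = np.cumsum(S * S)
    ciS = np.cumsum(np.arange(1, n + 1) * S)
    ci2 = np.cumsum(np.arange(1, n + 1, dtype=float) ** 2)
    k = np.arange(1, n, dtype=float)
    Sk = S[:-1]
    fwd = cS2[:-1] - (2.0 * Sk / k) * ciS[:-1] + (Sk * Sk / k**2) * ci2[:-1]
    R = np.cumsum(y[::-1])[::-1]
    m = np.arange(1, n + 1, dtype=float)[::-1]  # m_i = n - i + 1
    cR2 = np.cumsum((R * R)[::-1])[::-1]
    cmR = np.cumsum((m * R)[::-1])[::-1]
    cm2 = np.cumsum((m * m)[::-1])[::-1]
    Rk1 = R[1:]
    nk = n - np.arange(1, n, dtype=float)
    back = cR2[1:] - (2.0 * Rk1 / nk) * cmR[1:] + (Rk1 * Rk1 / nk**2) * cm2[1:]
    return fwd + back


def selfnorm_statistics(y: np.ndarray) -> tuple[float, float]:
    """The self-normalized sum and max statistics (S_{n,q}, M_{n,q}).

    S = sum_k (1/w_k) C_k^2 and M = max_k (n/w_k) C_k^2 with C_k the
    centred partial sum and w_k from :func:`selfnorm_weights`.  Both are
    invariant to location and scale changes of the series.  Splits with
    w_k = 0 and C_k = 0 (0/0) are dropped; a nonzero C_k over a zero
    weight is degenerate.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise InvalidInputError("self-normalized statistics need n >= 4")
    C = _centered_partial_sums(y)
    w = _selfnorm_weights_all(y)
    zero = w <= 1e-300
    if np.any(zero & (np.abs(C) > 1e-12 * max(1.0, float(np.abs(y).max())))):
        raise DegenerateDataError("zero self-normalizer with nonzero CUSUM at some split")
    keep = ~zero
    if not np.any(keep):
        raise DegenerateDataError("series is constant; self-normalized statistics undefined")
    ratio = C[keep] ** 2 / w[keep]
    return float(np.sum(ratio)), float(n * np.max(ratio))


# -- saddle-point approximation (Poisson mixed model) ----------------------

def log_saddlepoint_integral(rho: float, a: float, b: float, nu2: float) -> float:
    """Log of the saddle-point approximation to I(rho; a, b, nu2).

    I = int exp(-b e^u + a u - (u - rho)^2 / (2 nu2)) du is the marginal
    likelihood integral of a Poisson observation with a normal latent
    effect.  Expanding the exponent around the saddle point
    c = log(a/b) of phi(u) = a u - b e^u gives

        I ~ (a / (b e))^a sqrt(2 pi / a) exp(-(c - rho)^2 / (2 nu2)).

    Returned on the log scale to avoid overflow for large a.
    """
    if a <= 0 or b <= 0 or nu2 <= 0:
        raise InvalidInputError("a, b and nu2 must all be positive")
    c = math.log(a / b)
    return a * (c - 1.0) + 0.5 * math.log(2.0 * math.pi / a) - (c - rho) ** 2 / (2.0 * nu2)


def saddlepoint_integral(rho: float, a: float, b: float, nu2: float) -> float:
    """Saddle-point approximation to I(rho; a, b, nu2) on the natural scale."""
    return math.exp(log_saddlepoint_integral(rho, a, b, nu2))


def numeric_marginal_integral(rho: float, a: float, b: float, nu2: float) -> float:
    """Adaptive-quadrature oracle for I(rho; a, b, nu2), shifted to avoid
    overflow: returns the integral on the natural scale divided by
    exp(M), alongside M, as (value, M) folded into log space."""
    if a <= 0 or b <= 0 or nu2 <= 0:
        raise InvalidInputError("a, b and nu2 must all be positive")
    c = math.log(a / b)

    def exponent(u: float) -> float:
        return a * u - b * math.exp(u) - (u - rho) ** 2 / (2.0 * nu2)

    M = exponent(c)
    val, _ = _quad(lambda u: math.exp(exponent(u) - M), c - 40.0 * max(1.0, math.sqrt(nu2)),
                   c + 40.0 * max(1.0, math.sqrt(nu2)), limit=400)
    return math.log(val) + M
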