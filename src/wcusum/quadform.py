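"""Null distributions of the quadratic weighted CUSUM statistic.

Under independent normal sampling with known variance the statistic
``S_n(Y; tau, 2)/sigma^2`` is distributed exactly as a weighted sum of
independent chi-square(1) variables,

    sum_k lambda_k(tau) Z_k^2,

with closed-form eigenvalues

    lambda_k = 1 / (k (k + 1))        (tau = n/2, "center")
    lambda_k = 1 / (2k (2k + 1))      (tau = 0 or n, "left"/"right")

for k = 1, ..., n-1.  The left and right families share one spectrum,
so they share one null distribution.  As n grows the spectrum extends
without altering earlier terms, and the series limits coincide with the
Karhunen-Loeve expansions of weighted squared Brownian-bridge integrals
(the center case is the classical Anderson-Darling limit).

The CDF, p-values and quantiles are computed by Imhof's method: exact
numerical inversion of the characteristic function,

    F(x) = 1/2 - (1/pi) * int_0^inf sin(theta(u)) / (u rho(u)) du,
    theta(u) = (1/2) sum_k arctan(lambda_k u) - x u / 2,
    rho(u)   = prod_k (1 + lambda_k^2 u^2)^{1/4}.

The infinite-n spectrum is represented by explicit truncation after K
terms plus a deterministic shift equal to the exactly-known tail mass
(the tail's expectation); the truncation point is chosen so that the
standard deviation of the neglected centred fluctuation is below a
user-visible ``epsilon`` (default 1e-8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import InvalidInputError, NumericalError
from .weights import TAU_KINDS

__all__ = [
    "EigenSpectrum",
    "QuadFormDist",
    "exact_eigenvalues",
    "limit_spectrum",
    "null_distribution",
    "imhof_cdf",
    "critical_value",
    "pvalue",
]

#: Exact total spectral mass of the infinite series (telescoping sums):
#: center: sum 1/(k(k+1)) = 1;  left/right: sum 1/(2k(2k+1)) = 1 - log 2.
TOTAL_MASS = {"center": 1.0, "left": 1.0 - math.log(2.0), "right": 1.0 - math.log(2.0)}


def _lambda_closed_form(k: np.ndarray, tau_kind: str) -> np.ndarray:
    if tau_kind == "center":
        return 1.0 / (k * (k + 1.0))
    return 1.0 / (2.0 * k * (2.0 * k + 1.0))


@dataclass(frozen=True)
class EigenSpectrum:
    """Nonzero eigenvalues of the null quadratic form, sorted descending.

    ``n`` is the source sample size, or ``None`` for a truncated
    representation of the infinite series, in which case ``tail_mass``
    carries the exactly-known mass of the dropped tail (folded into the
    distribution as a deterministic shift) and ``truncation_count`` the
    number of retained terms.
    """

    lambdas: np.ndarray
    tau_kind: str
    n: int | None = None
    tail_mass: float = 0.0

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or lam.size == 0:
            raise InvalidInputError("spectrum must be a nonempty 1-d array")
        if np.any(lam <= 0):
            raise InvalidInputError("eigenvalues must be strictly positive")
        if np.any(np.diff(lam) > 0):
            raise InvalidInputError("eigenvalues must be sorted descending")
        object.__setattr__(self, "lambdas", lam)

    @property
    def truncation_count(self) -> int:
        return int(self.lambdas.size)

    @property
    def is_limit(self) -> bool:
        return self.n is None

    @property
    def mean(self) -> float:
        """Mean of the distribution: total retained mass plus tail shift."""
        return float(self.lambdas.sum() + self.tail_mass)

    @property
    def variance(self) -> float:
        return float(2.0 * np.sum(self.lambdas**2))


def exact_eigenvalues(n: int, tau_kind: str) -> EigenSpectrum:
    """Closed-form spectrum of Q for a series of length ``n``.

    Returns the n-1 nonzero eigenvalues (Q's remaining eigenvalue is 0,
    from the constant vector in its null space).
    """
    if int(n) != n or n < 2:
        raise InvalidInputError(f"n must be an integer >= 2, got {n}")
    if tau_kind not in TAU_KINDS:
        raise InvalidInputError(f"tau_kind must be one of {TAU_KINDS}, got {tau_kind!r}")
    k = np.arange(1, int(n), dtype=float)
    return EigenSpectrum(lambdas=_lambda_closed_form(k, tau_kind), tau_kind=tau_kind, n=int(n))


def limit_spectrum(tau_kind: str, epsilon: float = 1e-8, max_terms: int = 2_000_000) -> EigenSpectrum:
    """Truncated representation of the infinite (n -> inf) spectrum.

    Keeps the first K eigenvalues and accounts for the dropped tail by
    its exact mass (a deterministic shift).  K is the smallest count for
    which the standard deviation ``sqrt(2 sum_{k>K} lambda_k^2)`` of the
    neglected centred fluctuation is below ``epsilon``, so the total
    distributional error of the representation is O(epsilon).
    Decreasing epsilon increases K monotonically.
    """
    if tau_kind not in TAU_KINDS:
        raise InvalidInputError(f"tau_kind must be one of {TAU_KINDS}, got {tau_kind!r}")
    if not epsilon > 0:
        raise InvalidInputError("epsilon must be positive")
    # lambda_k <= c/k^2 with c=1 (center) or 1/4 (left/right); the tail
    # sum of squares is bounded by c^2/(3K^3), giving a closed-form K.
    c = 1.0 if tau_kind == "center" else 0.25
    K = int(math.ceil((2.0 * c * c / (3.0 * epsilon * epsilon)) ** (1.0 / 3.0))) + 1
    K = min(max(K, 8), max_terms)
    k = np.arange(1, K + 1, dtype=float)
    lam = _lambda_closed_form(k, tau_kind)
    if tau_kind == "center":
        tail = 1.0 / (K + 1.0)  # telescoping remainder
    else:
        tail = TOTAL_MASS[tau_kind] - float(np.sum(lam[::-1]))
        tail = max(tail, 0.0)
    return EigenSpectrum(lambdas=lam, tau_kind=tau_kind, n=None, tail_mass=tail)


class QuadFormDist:
    """Distribution of ``sum_k lambda_k Z_k^2 (+ shift)`` via Imhof's method.

    Provides the CDF, upper-tail p-value and quantile of a positively
    weighted sum of independent chi-square(1) variables.  The Imhof
    integral is evaluated by adaptive quadrature on (0, U], with U
    doubled until the integrand envelope ``1/(u rho(u))`` falls below
    a small fraction of the accuracy target.

    For spectra with very many terms the tiny eigenvalues enter
    ``theta`` and ``log rho`` through their first-order expansions
    (``arctan z ~ z``, ``log(1+z^2) ~ z^2`` for small ``z``), using
    precomputed suffix sums; the neglected cubic remainders are bounded
    well below the quadrature tolerance.
    """

    def __init__(self, spectrum: EigenSpectrum, tol: float = 1e-8):
        self.spectrum = spectrum
        self.tol = float(tol)
        lam = spectrum.lambdas
        self._lam = lam
        self._lam2 = lam * lam
        self._lam3 = self._lam2 * lam
        # suffix sums for the small-argument linearisation (descending order)
        def _suffix(v: np.ndarray) -> np.ndarray:
            return np.concatenate([np.cumsum(v[::-1])[::-1], [0.0]])

        self._suf1 = _suffix(lam)
        self._suf2 = _suffix(self._lam2)
        self._suf3 = _suffix(self._lam3)
        self._shift = spectrum.tail_mass

    # -- Imhof integrand pieces -------------------------------------------
    _SMALL = 1e-4  # lambda*u below this uses the linearised contribution

    def _pieces(self, u: float, x: float):
        """theta, log rho and their u-derivatives at u (vector head +
        linearised tail of the spectrum)."""
        lam = self._lam
        m = int(np.searchsorted(-lam, -self._SMALL / u))
        h = lam[:m]
        hu = h * u
        den = 1.0 + hu * hu
        theta = 0.5 * (float(np.arctan(hu).sum()) + u * self._suf1[m]) - 0.5 * x * u
        logrho = 0.25 * (float(np.log1p(hu * hu).sum()) + u * u * self._suf2[m])
        dtheta = 0.5 * (float((h / den).sum()) + self._suf1[m]) - 0.5 * x
        dlogrho = 0.5 * (float((h * hu / den).sum()) / u if m else 0.0) + 0.5 * u * self._suf2[m]
        d2theta = -float((self._lam3[:m] * u / den**2).sum()) - u * self._suf3[m]
        return theta, logrho, dtheta, dlogrho, d2theta

    def _integrand(self, u: float, x: float) -> float:
        theta, logrho, *_ = self._pieces(u, x)
        return math.sin(theta) * math.exp(-logrho) / u

    def _tail(self, U: float, x: float) -> tuple[float, float]:
        """Two integration-by-parts terms for int_U^inf sin(theta) g du
        plus a bound on the remainder; g = exp(-log rho)/u."""
        theta, logrho, dth, dlr, d2th = self._pieces(U, x)
        g = math.exp(-logrho) / U
        m = self._lam.size
        env_bound = g * U * 2.0 / m if m else g * U  # int of the envelope
        if abs(dth) < 1e-3:
            return 0.0, env_bound
        dg = g * (-1.0 / U - dlr)
        h = g / dth
        dh = (dg * dth - g * d2th) / dth**2
        correction = h * math.cos(theta) - (dh / dth) * math.sin(theta)
        # remainder after two IBP passes shrinks by roughly |dh/(h dth)| again
        remainder = abs(dh / dth) * (abs(dh) / max(abs(h), 1e-300) / abs(dth) + 2.0 / (U * abs(dth)))
        return correction, min(env_bound, abs(remainder))

    def _upper_limit(self, x: float, target: float) -> tuple[float, float]:
        """Pick U so that the analytic tail correction leaves error < target."""
        U = 8.0
        while U < 1e14:
            correction, bound = self._tail(U, x)
            if bound < target:
                return U, correction
            U *= 2.0
        raise NumericalError("Imhof integrand envelope did not decay; spectrum may be degenerate")

    def cdf(self, x: float) -> float:
        """P(sum lambda_k Z_k^2 + shift <= x), absolute error ~ tol."""
        x = float(x) - self._shift
        if x <= 0:
            return 0.0
        U, tail_correction = self._upper_limit(x, 0.03 * self.tol * math.pi)
        val, err = quad(self._integrand, 0.0, U, args=(x,), epsabs=0.1 * self.tol,
                        epsrel=1e-10, limit=3000)
        if not np.isfinite(val) or err > max(50 * self.tol, 1e-5):
            raise NumericalError(
                f"Imhof quadrature did not converge (x={x:g}, estimate={val:g}, err={err:g})"
            )
        return float(min(1.0, max(0.0, 0.5 - (val + tail_correction) / math.pi)))

    def pvalue(self, observed: float) -> float:
        """Upper-tail probability ``1 - cdf(observed)``, clipped to [0, 1]."""
        if observed < 0:
            raise InvalidInputError("observed statistic must be nonnegative")
        return float(min(1.0, max(0.0, 1.0 - self.cdf(observed))))

    def quantile(self, p: float, bracket_hint: float | None = None) -> float:
        """The x with cdf(x) = p, by bracketing root-finding.

        ``bracket_hint`` (e.g. a neighbouring sample size's quantile)
        narrows the initial bracket to speed up the search.
        """
        if not 0.0 < p < 1.0:
            raise InvalidInputError(f"probability must lie in (0, 1), got {p}")
        mean, var = self.spectrum.mean, self.spectrum.variance
        lo, hi = 0.0, mean + 10.0 * math.sqrt(var)
        if bracket_hint is not None and bracket_hint > 0:
            lo, hi = 0.8 * bracket_hint, 1.25 * bracket_hint
            while self.cdf(lo) > p and lo > 1e-12:
                lo *= 0.5
        while self.cdf(hi) < p:
            lo, hi = hi, 2.0 * hi
            if hi > 1e8 * (mean + 1.0):
                raise NumericalError("quantile bracket expansion failed")
        return float(brentq(lambda x: self.cdf(x) - p, lo, hi, xtol=1e-8, rtol=1e-12))


# -- convenience functional layer ------------------------------------------

@lru_cache(maxsize=256)
def null_distribution(n: int | None, tau_kind: str, epsilon: float = 1e-8) -> QuadFormDist:
    """Cached null distribution for sample size ``n`` (None = limit)."""
    if n is None:
        return QuadFormDist(limit_spectrum(tau_kind, epsilon=epsilon))
    return QuadFormDist(exact_eigenvalues(n, tau_kind))


@lru_cache(maxsize=4096)
def null_critical_value(n: int | None, tau_kind: str, p: float) -> float:
    """Cached quantile of the null distribution (None = limit spectrum)."""
    return null_distribution(n, tau_kind).quantile(p)


def imhof_cdf(dist: QuadFormDist, x: float) -> float:
    return dist.cdf(x)


def critical_value(dist: QuadFormDist, p: float, bracket_hint: float | None = None) -> float:
    return dist.quantile(p, bracket_hint=bracket_hint)


def pvalue(dist: QuadFormDist, observed: float) -> float:
    return dist.pvalue(observed)
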