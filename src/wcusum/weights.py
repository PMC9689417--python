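"""Quadratic CUSUM weights and the associated quadratic-form matrix.

A weighted CUSUM statistic down-weights candidate split points ``k``
through a quadratic weight ``w_k(tau)`` whose symmetry centre ``tau``
encodes a prior guess of the change location:

* ``tau = 0``   ("left"):   ``w_k = (n + k)(n - k)`` — the reciprocal
  weight is largest near ``k = n - 1``, favouring late changes;
* ``tau = n/2`` ("center"): ``w_k = k(n - k)`` — the likelihood-ratio
  weighting, favouring central changes;
* ``tau = n``   ("right"):  ``w_k = k(2n - k)`` — favouring early changes.

All three are instances of the single formula
``w_k(tau) = -(k - tau)^2 + max(tau^2, (n - tau)^2)``, which also equals
the expected absorption time of a simple random walk started at the
corresponding state.  For the quadratic exponent (gamma = 2) the
statistic is the Gaussian quadratic form ``Y'QY`` with ``n^2 Q = AA'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, UnsupportedOperationError

TAU_KINDS = ("left", "center", "right")


@dataclass(frozen=True)
class WeightScheme:
    """A quadratic weight family: series length, prior location, exponent.

    Parameters
    ----------
    n : int
        Series length (number of time points), at least 2.
    tau_kind : {"left", "center", "right"}
        Categorical prior change location tau in {0, n/2, n}.  Kept
        categorical so odd ``n`` needs no n/2 rounding convention.
    gamma : float
        Positive exponent applied to the absolute partial sums.  The
        quadratic-form representation exists only for ``gamma == 2``.
    """

    n: int
    tau_kind: str = "center"
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 2:
            raise InvalidInputError(f"series length n must be an integer >= 2, got {self.n}")
        if self.tau_kind not in TAU_KINDS:
            raise InvalidInputError(f"tau_kind must be one of {TAU_KINDS}, got {self.tau_kind!r}")
        if not self.gamma > 0:
            raise InvalidInputError(f"gamma must be positive, got {self.gamma}")
        object.__setattr__(self, "n", int(self.n))

    @property
    def tau(self) -> float:
        """The numeric prior location tau in {0, n/2, n}."""
        return {"left": 0.0, "center": self.n / 2.0, "right": float(self.n)}[self.tau_kind]

    def weights(self) -> np.ndarray:
        return compute_weights(self)


def compute_weights(scheme: WeightScheme) -> np.ndarray:
    """Weight vector ``(w_1, ..., w_{n-1})`` for the given scheme.

    Returns strictly positive weights; ``center`` weights are symmetric
    (``w_k = w_{n-k}``) and left/right mirror each other
    (``w_k(left) = w_{n-k}(right)``).
    """
    n = scheme.n
    k = np.arange(1, n, dtype=float)
    if scheme.tau_kind == "left":
        w = (n + k) * (n - k)
    elif scheme.tau_kind == "center":
        w = k * (n - k)
    else:  # right
        w = k * (2 * n - k)
    return w


@dataclass(frozen=True)
class QuadFormMatrix:
    """The symmetric PSD matrix Q with ``S_n(Y; tau, 2) = Y'QY``.

    ``A`` holds the generating columns ``A_k`` (``n^2 Q = AA'``); Q is
    rank n-1 and annihilates the constant vector.
    """

    Q: np.ndarray
    A: np.ndarray
    scheme: WeightScheme = field(repr=False)

    def eigenvalues(self) -> np.ndarray:
        """Numerical eigenvalues of Q, sorted descending."""
        vals = np.linalg.eigvalsh(self.Q)
        return vals[::-1]


def build_Q(scheme: WeightScheme) -> QuadFormMatrix:
    """Construct Q and its generating columns for the quadratic case.

    Column ``A_k`` has first ``k`` entries ``p_k^{1/2} (n - k)`` and the
    remaining ``n - k`` entries ``-p_k^{1/2} k`` with ``p_k = 1/w_k``,
    so each column is orthogonal to the constant vector by construction.
    """
    if scheme.gamma != 2:
        raise UnsupportedOperationError(
            f"the quadratic-form matrix is defined only for gamma=2, got gamma={scheme.gamma}"
        )
    n = scheme.n
    w = compute_weights(scheme)
    p_sqrt = 1.0 / np.sqrt(w)
    A = np.zeros((n, n - 1))
    for k in range(1, n):
        A[:k, k - 1] = p_sqrt[k - 1] * (n - k)
        A[k:, k - 1] = -p_sqrt[k - 1] * k
    Q = (A @ A.T) / (n * n)
    Q = 0.5 * (Q + Q.T)  # enforce exact symmetry against rounding
    return QuadFormMatrix(Q=Q, A=A, scheme=scheme)
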