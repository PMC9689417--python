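"""Monte-Carlo reference samples for Brownian-bridge limit functionals.

Two families of limits have no closed-form null distribution and are
calibrated here by simulating a discretized Brownian bridge
``U(t) = B(t) - t B(1)`` on a regular grid:

* the self-normalized statistics, whose limits are
  ``int_0^1 U(t)^2 / {D1(0,t) + D2(t,1)} dt`` and its max-over-t
  analogue, where D1/D2 are the within-segment squared-bridge integrals
  of the two candidate segments;
* the graph edge-count statistics, whose limits are
  ``int U(t)^2 psi(t) dt + const`` (gamma = 1, the constant is -1 for
  the center weight and log 2 - 1 for left/right) and
  ``int {U(t)^2 - t(1-t)}^2 psi(t) dt`` (gamma = 2), with
  psi(t) = 1/{t(1-t)} (center), 1/(1-t^2) (left), 1/{t(2-t)} (right).

Samples are generated once per process from a fixed seed (default
20221652) and cached; all p-values and quantiles derived from them are
therefore reproducible from code alone.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .errors import InvalidInputError
from .weights import TAU_KINDS

DEFAULT_SEED = 20221652
DEFAULT_GRID = 2000
DEFAULT_REPS = 100_000

#: Additive constants of the gamma=1 graph limits: the expectation
#: identity E int U^2 psi dt = sum_k lambda_k cancels them to mean ~0.
GAMMA1_CONST = {"center": -1.0, "left": np.log(2.0) - 1.0, "right": np.log(2.0) - 1.0}


def psi_weight(t: np.ndarray, tau_kind: str) -> np.ndarray:
    """The limiting weight function psi(t) on (0, 1) for each family."""
    if tau_kind == "center":
        return 1.0 / (t * (1.0 - t))
    if tau_kind == "left":
        return 1.0 / (1.0 - t * t)
    if tau_kind == "right":
        return 1.0 / (t * (2.0 - t))
    raise InvalidInputError(f"tau_kind must be one of {TAU_KINDS}, got {tau_kind!r}")


def _bridge_batch(rng: np.ndarray, reps: int, m: int) -> np.ndarray:
    """reps x m matrix of B(t_i) on t_i = i/m, i = 1..m."""
    inc = rng.standard_normal((reps, m)) / np.sqrt(m)
    return np.cumsum(inc, axis=1)


def _selfnorm_functionals(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integral and max functionals of U^2/(D1+D2) from bridge paths W."""
    reps, m = W.shape
    i = np.arange(1, m + 1, dtype=float)
    t = i / m
    U = W - t * W[:, -1][:, None]
    # D1(t_k) = (1/m) sum_{i<=k} (W_i - (i/k) W_k)^2 via prefix sums
    cW2 = np.cumsum(W * W, axis=1)
    ciW = np.cumsum(i * W, axis=1)
    ci2 = np.cumsum(i * i)
    k = i
    D1 = (cW2 - (2.0 * W / k) * ciW + (W * W / k**2) * ci2) / m
    # D2(t_k) = (1/m) sum_{i>k} (G_i - ((m-i)/(m-k)) G_k)^2, G_i = B(1)-B(t_i)
    G = W[:, -1][:, None] - W
    mi = (m - i)
    sG2 = np.cumsum((G * G)[:, ::-1], axis=1)[:, ::-1]
    smG = np.cumsum((mi * G)[:, ::-1], axis=1)[:, ::-1]
    sm2 = np.cumsum((mi * mi)[::-1])[::-1]
    D2 = np.zeros_like(W)
    mk = m - k[:-1]
    D2[:, :-1] = (sG2[:, 1:] - (2.0 * G[:, :-1] / mk) * smG[:, 1:]
                  + (G[:, :-1] ** 2 / mk**2) * sm2[1:]) / m
    denom = D1[:, :-1] + D2[:, :-1]
    ratio = U[:, :-1] ** 2 / denom
    integral = ratio.sum(axis=1) / m
    maximum = ratio.max(axis=1)
    return integral, maximum


@lru_cache(maxsize=4)
def selfnorm_limit_samples(seed: int = DEFAULT_SEED, grid: int = DEFAULT_GRID,
                           reps: int = DEFAULT_REPS) -> tuple[np.ndarray, np.ndarray]:
    """Sorted Monte-Carlo samples of the (sum, max) self-normalized limits."""
    rng = np.random.default_rng(seed)
    ints, maxs = [], []
    batch = max(1, min(reps, 100_000_000 // (grid * 16)))
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        W = _bridge_batch(rng, b, grid)
        s_int, s_max = _selfnorm_functionals(W)
        ints.append(s_int)
        maxs.append(s_max)
        done += b
    return np.sort(np.concatenate(ints)), np.sort(np.concatenate(maxs))


@lru_cache(maxsize=16)
def graph_limit_samples(tau_kind: str, gamma: int, seed: int = DEFAULT_SEED,
                        grid: int = DEFAULT_GRID, reps: int = DEFAULT_REPS) -> np.ndarray:
    """Sorted Monte-Carlo sample of the graph-statistic limit functional."""
    if gamma not in (1, 2):
        raise InvalidInputError(f"graph statistics support gamma in {{1, 2}}, got {gamma}")
    rng = np.random.default_rng(seed + 7 * gamma)
    t = (np.arange(1, grid + 1, dtype=float) - 0.5) / grid  # midpoint grid
    psi = psi_weight(t, tau_kind)
    out = []
    batch = max(1, min(reps, 200_000_000 // (grid * 16)))
    done = 0
    while done < reps:
        b = min(batch, reps - done)
        inc = rng.standard_normal((b, grid)) / np.sqrt(grid)
        W = np.cumsum(inc, axis=1)
        U = W - t * W[:, -1][:, None]
        if gamma == 1:
            vals = (U * U * psi).sum(axis=1) / grid + GAMMA1_CONST[tau_kind]
        else:
            vals = (((U * U - t * (1.0 - t)) ** 2) * psi).sum(axis=1) / grid
        out.append(vals)
        done += b
    return np.sort(np.concatenate(out))


def mc_pvalue(sorted_sample: np.ndarray, observed: float) -> float:
    """Upper-tail Monte-Carlo p-value with the standard +1 correction."""
    n = sorted_sample.size
    ge = n - np.searchsorted(sorted_sample, observed, side="left")
    return float((ge + 1.0) / (n + 1.0))


def mc_quantile(sorted_sample: np.ndarray, p: float) -> float:
    if not 0.0 < p < 1.0:
        raise InvalidInputError(f"probability must lie in (0, 1), got {p}")
    return float(np.quantile(sorted_sample, p))
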