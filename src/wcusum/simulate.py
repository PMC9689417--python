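"""Synthetic data generators and the Monte-Carlo power-study harness.

The generators emulate the designs used to study the weighted CUSUM
tests: an abrupt normal mean shift across high-dimensional replicates,
a post-change two-component normal mixture, a Poisson mixed model with
a per-time latent effect, AR(1) weakly dependent noise, and a toy
grayscale image sequence in which a bright blob appears and later
disappears (two change points near the ends, mimicking an object
entering and leaving a camera's field of view).

The power study generates ``reps`` independent datasets from
per-replicate substreams of a single master seed (substream r is
``SeedSequence(seed, spawn_key=(r,))``), applies every requested method
to the *same* data within a replicate (common random numbers, so
method comparisons are low-variance), and reports rejection
percentages with binomial standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import quadform, stats
from .errors import InvalidInputError
from .graph import GraphCUSUM
from .series import SeriesData
from .weights import WeightScheme

__all__ = [
    "SimConfig",
    "PowerReport",
    "gen_normal_shift",
    "gen_normal_mixture",
    "gen_poisson_mixed",
    "gen_ar1_weakdep",
    "gen_image_sequence",
    "generate",
    "power_study",
    "WC_METHODS",
]

WC_METHODS = ("wc_left", "wc_center", "wc_right", "graph_euclidean", "graph_pseudo")

#: The two post-change mixture configurations of the study design,
#: (weights, means); unit variances.  Implied mean shifts 0.1 and 0.2.
CANONICAL_MIXTURES = (((0.5, 0.5), (0.0, 0.2)), ((0.8, 0.2), (0.0, 1.0)))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation cell.

    Defaults follow the reference study design: n = 40 time points,
    q = 50 replicates, change at k* = n/2, magnitude delta = 0.2,
    200 Monte-Carlo replications at level 0.05.
    """

    n: int = 40
    q: int = 50
    k_star: int = 20
    delta: float = 0.2
    model: str = "normal_shift"
    reps: int = 200
    level: float = 0.05
    seed: int = 0
    methods: tuple = ("wc_left", "wc_center", "wc_right")
    # model-specific knobs
    mixture_weights: tuple = (0.8, 0.2)
    mixture_means: tuple = (0.0, 1.0)
    phi: float = 0.3
    nu2: float = 0.1
    rho_minus: float = 0.0
    rho_plus: float = 0.5
    image_shape: tuple = (16, 16)
    blob_intensity: float = 1.0
    k1: int | None = None
    k2: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.k_star <= self.n - 1:
            raise InvalidInputError(f"k_star must lie in [1, n-1], got {self.k_star}")
        if self.reps < 1:
            raise InvalidInputError("reps must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise InvalidInputError("level must lie in (0, 1)")
        unknown = set(self.methods) - set(WC_METHODS)
        if unknown:
            raise InvalidInputError(f"unknown methods: {sorted(unknown)}")


def _rng_for(config: SimConfig, rep: int) -> np.random.Generator:
    """Documented substream scheme: SeedSequence(seed, spawn_key=(rep,))."""
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(rep,)))


def gen_normal_shift(config: SimConfig, rng: np.random.Generator) -> SeriesData:
    """i.i.d. N(0,1) entries; rows after k* have mean delta instead of 0."""
    Y = rng.standard_normal((config.n, config.q))
    Y[config.k_star:, :] += config.delta
    return SeriesData(Y)


def gen_normal_mixture(config: SimConfig, rng: np.random.Generator) -> SeriesData:
    """Standard normal before k*; two-component normal mixture after.

    Component variances are fixed at 1; the implied mean shift is the
    weighted mean of the component means.
    """
    w = np.asarray(config.mixture_weights, dtype=float)
    mu = np.asarray(config.mixture_means, dtype=float)
    if w.size != mu.size or not np.isclose(w.sum(), 1.0) or np.any(w < 0):
        raise InvalidInputError("mixture weights must be nonnegative and sum to 1")
    Y = rng.standard_normal((config.n, config.q))
    shape = (config.n - config.k_star, config.q)
    comp = rng.choice(w.size, size=shape, p=w)
    Y[config.k_star:, :] += mu[comp]
    return SeriesData(Y)


def gen_poisson_mixed(config: SimConfig, rng: np.random.Generator) -> SeriesData:
    """Counts with conditional mean exp(rho_i + U_i), U_i ~ N(0, nu2).

    The shared per-row latent effect U_i induces within-row dependence
    and overdispersion; rho steps from rho_minus to rho_plus at k*.
    """
    if config.nu2 < 0:
        raise InvalidInputError("nu2 must be nonnegative")
    rho = np.full(config.n, config.rho_minus)
    rho[config.k_star:] = config.rho_plus
    U = rng.normal(0.0, np.sqrt(config.nu2), size=config.n) if config.nu2 > 0 else np.zeros(config.n)
    lam = np.exp(rho + U)
    Y = rng.poisson(lam[:, None], size=(config.n, config.q)).astype(float)
    return SeriesData(Y)


def gen_ar1_weakdep(config: SimConfig, rng: np.random.Generator) -> SeriesData:
    """Columns follow AR(1) in time (so row means do too), plus a mean
    shift of delta after k*; phi = 0 recovers the normal-shift model."""
    if not abs(config.phi) < 1:
        raise InvalidInputError(f"AR(1) coefficient must satisfy |phi| < 1, got {config.phi}")
    from scipy.signal import lfilter

    eps = rng.standard_normal((config.n, config.q))
    eps[0] /= np.sqrt(1.0 - config.phi**2)  # stationary start
    Y = lfilter([1.0], [1.0, -config.phi], eps, axis=0)
    Y[config.k_star:, :] += config.delta
    return SeriesData(Y)


def gen_image_sequence(config: SimConfig, rng: np.random.Generator) -> SeriesData:
    """Noise frames with a bright Gaussian blob present on frames
    (k1, k2] — an object arriving early and departing late.

    Frames are h x w grayscale images flattened to q = h*w pixels.
    Defaults put k1 near n/10 and k2 near 9n/10 so that the arrival is
    an early change and the departure a late one.
    """
    h, w = config.image_shape
    q = h * w
    n = config.n
    k1 = config.k1 if config.k1 is not None else max(1, round(0.1 * n))
    k2 = config.k2 if config.k2 is not None else min(n - 1, round(0.9 * n))
    if not 1 <= k1 < k2 <= n - 1:
        raise InvalidInputError(f"need 1 <= k1 < k2 <= n-1, got k1={k1}, k2={k2}")
    frames = rng.standard_normal((n, h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    blob = np.exp(-(((yy - cy) / (0.15 * h)) ** 2 + ((xx - cx) / (0.15 * w)) ** 2))
    frames[k1:k2] += config.blob_intensity * blob
    return SeriesData(frames.reshape(n, q))


_GENERATORS = {
    "normal_shift": gen_normal_shift,
    "normal_mixture": gen_normal_mixture,
    "poisson_mixed": gen_poisson_mixed,
    "ar1_weakdep": gen_ar1_weakdep,
    "image_sequence": gen_image_sequence,
}


def generate(config: SimConfig, rng: np.random.Generator | None = None) -> SeriesData:
    """Generate one dataset from the configured model."""
    if config.model not in _GENERATORS:
        raise InvalidInputError(f"unknown model {config.model!r}; choose from {sorted(_GENERATORS)}")
    if rng is None:
        rng = _rng_for(config, 0)
    return _GENERATORS[config.model](config, rng)


@dataclass(frozen=True)
class PowerReport:
    """Rejection percentages per method for one simulation cell."""

    table: pd.DataFrame
    config: SimConfig = field(repr=False, compare=False)

    def power(self, method: str) -> float:
        row = self.table.loc[self.table["method"] == method]
        if row.empty:
            raise InvalidInputError(f"method {method!r} not in report")
        return float(row["power_pct"].iloc[0])

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def _wc_reject(rm: np.ndarray, scheme: WeightScheme, crit: float) -> tuple[bool, float]:
    stat = stats.wc_statistic(rm, scheme) / stats.variance_estimate(rm)
    return stat > crit, stat


def power_study(config: SimConfig) -> PowerReport:
    """Monte-Carlo rejection rates of the requested methods.

    Exact finite-n critical values calibrate the weighted CUSUM tests;
    the graph tests use their asymptotic Monte-Carlo calibration.  All
    methods see the same generated data within each replicate.
    """
    n, level = config.n, config.level
    schemes = {m: WeightScheme(n, m.split("_", 1)[1], 2.0)
               for m in config.methods if m.startswith("wc_")}
    crits = {m: quadform.null_critical_value(n, s.tau_kind, 1.0 - level)
             for m, s in schemes.items()}
    graph_methods = [m for m in config.methods if m.startswith("graph_")]
    graph_crit = 0.0
    if graph_methods:
        from . import bridge
        from .graph import permutation_null_sample

        null = permutation_null_sample(n, "center", 2, reps=5000)
        graph_crit = bridge.mc_quantile(null, 1.0 - level)

    rejections = {m: 0 for m in config.methods}
    for r in range(config.reps):
        rng = _rng_for(config, r)
        data = generate(config, rng)
        rm = data.row_means
        for m, s in schemes.items():
            rej, _ = _wc_reject(rm, s, crits[m])
            rejections[m] += rej
        for m in graph_methods:
            from .graph import edge_count_curve, graph_wc_statistic, normalize_graph_statistic
            from .graph import distance_matrix as _dm
            from .graph import shp_order as _shp

            metric = m.split("_", 1)[1]
            curve = edge_count_curve(_shp(_dm(data, metric)))
            normed = normalize_graph_statistic(
                graph_wc_statistic(curve, WeightScheme(n, "center", 2.0)), n, 2)
            rejections[m] += normed > graph_crit

    rows = []
    for m in config.methods:
        p_hat = rejections[m] / config.reps
        rows.append({
            "method": m,
            "model": config.model,
            "n": n,
            "q": config.q,
            "delta": config.delta,
            "k_star": config.k_star,
            "level": level,
            "reps": config.reps,
            "power_pct": 100.0 * p_hat,
            "se_pct": 100.0 * float(np.sqrt(p_hat * (1.0 - p_hat) / config.reps)),
        })
    return PowerReport(table=pd.DataFrame(rows), config=config)


def power_grid(base: SimConfig, **grids) -> pd.DataFrame:
    """Run power_study over a cartesian grid of config overrides.

    Example: ``power_grid(cfg, delta=[0.1, 0.2], k_star=[10, 20, 30])``.
    """
    import itertools

    keys = list(grids)
    frames = []
    for combo in itertools.product(*(grids[k] for k in keys)):
        cfg = replace(base, **dict(zip(keys, combo)))
        frames.append(power_study(cfg).table)
    return pd.concat(frames, ignore_index=True)
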