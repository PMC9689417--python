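"""Graph-based weighted CUSUM test via edge counts on a Hamiltonian path.

High-dimensional observations are treated as nodes of a graph with
pairwise distances; a short Hamiltonian path orders them by similarity.
For a candidate split k, the number of path edges joining the first k
time points to the rest, ``C_P(N_k, Nbar_k)``, is small when a change
makes the two segments internally similar.  Under the permutation null
the count has mean ``2k(n-k)/n`` and variance
``2k(n-k){2k(n-k)-n} / (n^3 - n^2)``, and the weighted CUSUM of the
centred counts,

    S_n(P; tau, gamma) = sum_k w_k(tau)^{-1} {2k(n-k)/n - C_P}^gamma,

converges (after norming) to Brownian-bridge functionals:
``sqrt(n/2) S_n(P; tau, 1)`` and ``S_n(P; tau, 2) / 2`` have the limits
sampled in :mod:`wcusum.bridge`.  The norming constants follow from the
permutation variance: the centred count at k = tn, divided by
sqrt(2n), converges to {B(t) - tB(1)}^2 - t(1-t).

The path is built by a deterministic heuristic (greedy edge insertion
with lexicographic tie-breaking, then best-improvement 2-opt), since
the shortest Hamiltonian path itself is NP-hard.

Calibration.  Under the null the time labels are exchangeable
conditional on the path, so the exact null law of the statistic is its
permutation distribution, which is cheap to sample (O(n) per draw) and
is the default calibration.  The Brownian-bridge asymptotic
calibration is also offered: its first two moments match the
permutation null exactly for gamma = 1 (the statistic is linear in the
centred counts), but for gamma = 2 the bridge-squared limit has a
heavier upper tail than the permutation null (whose per-split counts
are asymptotically normal by the combinatorial CLT), making the
asymptotic gamma = 2 test conservative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import bridge
from .errors import InvalidInputError
from .series import as_series_data
from .weights import WeightScheme, compute_weights

__all__ = [
    "DistanceMatrix",
    "PathOrder",
    "EdgeCountCurve",
    "distance_matrix",
    "shp_order",
    "edge_count_curve",
    "permutation_edge_moments",
    "graph_wc_statistic",
    "normalize_graph_statistic",
    "graph_limit_quantiles",
    "GraphCUSUM",
    "GraphTestResults",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with zero diagonal."""

    values: np.ndarray
    metric_kind: str = "euclidean"

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise InvalidInputError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise InvalidInputError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise InvalidInputError("distance matrix must have a zero diagonal")
        if np.any(d < 0):
            raise InvalidInputError("distances must be nonnegative")
        object.__setattr__(self, "values", d)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def distance_matrix(data, metric_kind: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between time points (rows).

    ``euclidean`` uses the full q-dimensional rows (sensitive to mean
    and variance changes); ``pseudo`` uses |difference of row means|
    (sensitive to mean changes only).  For q = 1 the two coincide.
    """
    data = as_series_data(data)
    if metric_kind == "euclidean":
        X = data.values
        sq = np.sum(X * X, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        d = np.sqrt(np.maximum(d2, 0.0))
    elif metric_kind == "pseudo":
        rm = data.row_means
        d = np.abs(rm[:, None] - rm[None, :])
    else:
        raise InvalidInputError(f"metric_kind must be 'euclidean' or 'pseudo', got {metric_kind!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=0.5 * (d + d.T), metric_kind=metric_kind)


@dataclass(frozen=True)
class PathOrder:
    """An ordering (v_1, ..., v_n) of the n nodes; edges are consecutive pairs."""

    order: np.ndarray
    length: float

    def __post_init__(self) -> None:
        o = np.asarray(self.order, dtype=int)
        if sorted(o.tolist()) != list(range(o.size)):
            raise InvalidInputError("path order must be a permutation of 0..n-1")
        object.__setattr__(self, "order", o)

    @property
    def n(self) -> int:
        return self.order.size


def _path_length(order: np.ndarray, D: np.ndarray) -> float:
    return float(D[order[:-1], order[1:]].sum())


def _greedy_edge_insertion(D: np.ndarray) -> np.ndarray:
    """Build a path by accepting cheapest edges that keep degrees <= 2
    and create no cycle; ties broken by lexicographic node pair."""
    n = D.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    order = np.lexsort((ju, iu, D[iu, ju]))
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    deg = np.zeros(n, dtype=int)
    adj: list[list[int]] = [[] for _ in range(n)]
    accepted = 0
    for e in order:
        a, b = int(iu[e]), int(ju[e])
        if deg[a] >= 2 or deg[b] >= 2:
            continue
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        parent[ra] = rb
        deg[a] += 1
        deg[b] += 1
        adj[a].append(b)
        adj[b].append(a)
        accepted += 1
        if accepted == n - 1:
            break
    # walk the path from the lowest-index endpoint
    endpoints = [v for v in range(n) if deg[v] <= 1]
    start = min(endpoints) if endpoints else 0
    path = [start]
    prev = -1
    cur = start
    while len(path) < n:
        nxt = [u for u in adj[cur] if u != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        path.append(cur)
    return np.asarray(path, dtype=int)


def _two_opt(order: np.ndarray, D: np.ndarray, max_passes: int = 200,
             tol: float = 1e-12) -> np.ndarray:
    """Best-improvement 2-opt for an open path, vectorised per pass."""
    n = order.size
    # pad with a virtual node at zero distance to everything so prefix
    # and suffix reversals fall out of the same formula
    D2 = np.zeros((n + 1, n + 1))
    D2[:n, :n] = D
    p = order.copy()
    for _ in range(max_passes):
        prev = np.concatenate(([n], p[:-1]))
        nxt = np.concatenate((p[1:], [n]))
        cut_prev = D2[prev, p]  # cost of edge (prev_i, p_i)
        cut_next = D2[p, nxt]   # cost of edge (p_j, next_j)
        delta = (D2[prev[:, None], p[None, :]] + D2[p[:, None], nxt[None, :]]
                 - cut_prev[:, None] - cut_next[None, :])
        delta[np.tril_indices(n)] = np.inf  # need i < j
        flat = int(np.argmin(delta))
        i, j = divmod(flat, n)
        if delta[i, j] >= -tol:
            break
        p[i:j + 1] = p[i:j + 1][::-1]
    return p


def shp_order(dist: DistanceMatrix) -> PathOrder:
    """Deterministic heuristic shortest-Hamiltonian-path ordering."""
    D = dist.values
    p = _greedy_edge_insertion(D)
    p = _two_opt(p, D)
    # canonical orientation: lower first label
    if p[0] > p[-1]:
        p = p[::-1].copy()
    return PathOrder(order=p, length=_path_length(p, D))


def permutation_edge_moments(n: int, k: np.ndarray | int):
    """Permutation-null mean and variance of the cross-edge count."""
    k = np.asarray(k, dtype=float)
    mean = 2.0 * k * (n - k) / n
    var = 2.0 * k * (n - k) * (2.0 * k * (n - k) - n) / (n**3 - n**2)
    return mean, var


@dataclass(frozen=True)
class EdgeCountCurve:
    """Cross-edge counts C_P(N_k, Nbar_k) for k = 1..n-1 plus null moments."""

    counts: np.ndarray
    n: int
    perm_mean: np.ndarray = field(default=None)
    perm_var: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.size != self.n - 1:
            raise InvalidInputError("edge-count curve must have n-1 entries")
        mean, var = permutation_edge_moments(self.n, np.arange(1, self.n))
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "perm_mean", mean)
        object.__setattr__(self, "perm_var", var)


def edge_count_curve(path: PathOrder, labels: np.ndarray | None = None) -> EdgeCountCurve:
    """Count path edges straddling each split of the time labels.

    ``labels`` gives the (0-based) time index of each node; by default
    node i is observation i.  An edge (u, v) crosses split k exactly
    when min(label) <= k < max(label) in 1-based terms, so the curve is
    the cumulative histogram of the edge label intervals.
    """
    n = path.n
    lab = np.arange(n) if labels is None else np.asarray(labels, dtype=int)
    a = lab[path.order[:-1]]
    b = lab[path.order[1:]]
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    diff = np.zeros(n + 1)
    np.add.at(diff, lo + 1, 1.0)
    np.add.at(diff, hi + 1, -1.0)
    counts = np.cumsum(diff)[1:n]  # k = 1..n-1
    return EdgeCountCurve(counts=counts, n=n)


def graph_wc_statistic(curve: EdgeCountCurve, scheme: WeightScheme) -> float:
    """sum_k w_k^{-1} {2k(n-k)/n - C_P(N_k, Nbar_k)}^gamma, gamma in {1, 2}.

    For gamma = 1 the signed centred counts are summed (the value can
    be negative); for gamma = 2 the statistic is nonnegative.
    """
    if scheme.gamma not in (1, 2):
        raise InvalidInputError(f"graph statistic supports gamma in {{1, 2}}, got {scheme.gamma}")
    if scheme.n != curve.n:
        raise InvalidInputError("scheme n does not match curve n")
    w = compute_weights(scheme)
    dev = curve.perm_mean - curve.counts
    return float(np.sum(dev ** scheme.gamma / w))


def normalize_graph_statistic(raw: float, n: int, gamma: int) -> float:
    """Finite-sample norming taking the raw statistic to its limit scale:
    sqrt(n/2) * S for gamma = 1, S / 2 for gamma = 2."""
    if gamma == 1:
        return math.sqrt(n / 2.0) * raw
    if gamma == 2:
        return raw / 2.0
    raise InvalidInputError(f"gamma must be 1 or 2, got {gamma}")


def graph_limit_quantiles(tau_kind: str, gamma: int, p: float, **mc_kwargs) -> float:
    """Monte-Carlo quantile of the normed statistic's limit distribution."""
    sample = bridge.graph_limit_samples(tau_kind, int(gamma), **mc_kwargs)
    return bridge.mc_quantile(sample, p)


@lru_cache(maxsize=64)
def permutation_null_sample(n: int, tau_kind: str, gamma: int, reps: int = 2000,
                            seed: int = bridge.DEFAULT_SEED) -> np.ndarray:
    """Sorted sample from the exact permutation null of the normed statistic.

    The null law depends only on (n, tau, gamma), not on the data or
    the particular path (relabelling any Hamiltonian path uniformly is
    the same as relabelling the identity path), so the sample is cached.
    """
    rng = np.random.default_rng(seed)
    scheme = WeightScheme(n, tau_kind, float(gamma))
    ident = PathOrder(order=np.arange(n), length=0.0)
    vals = np.empty(reps)
    for r in range(reps):
        curve = edge_count_curve(ident, labels=rng.permutation(n))
        vals[r] = normalize_graph_statistic(graph_wc_statistic(curve, scheme), n, int(gamma))
    vals.sort()
    return vals


@dataclass(frozen=True)
class GraphTestResults:
    """Outcome of the graph-based weighted CUSUM test."""

    statistic: float
    raw_statistic: float
    p_value: float
    critical_value: float
    level: float
    changepoint: int
    n: int
    tau_kind: str
    gamma: int
    metric_kind: str
    calibration: str
    path: PathOrder = field(repr=False, compare=False)

    @property
    def reject(self) -> bool:
        return self.statistic > self.critical_value

    def summary(self) -> str:
        from .model import _summary_table

        rows = [
            ("n (time points)", self.n),
            ("metric", self.metric_kind),
            ("tau_kind", self.tau_kind),
            ("gamma", self.gamma),
            ("calibration", self.calibration),
            ("statistic (normed)", self.statistic),
            (f"critical value ({1 - self.level:.3g})", self.critical_value),
            ("p-value", self.p_value),
            ("reject H0", str(self.reject)),
            ("changepoint estimate", self.changepoint),
        ]
        return _summary_table("Graph-based weighted CUSUM test", rows)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "raw_statistic": self.raw_statistic,
            "p_value": self.p_value,
            "critical_value": self.critical_value,
            "level": self.level,
            "k_hat": self.changepoint,
            "n": self.n,
            "tau": self.tau_kind,
            "gamma": self.gamma,
            "metric": self.metric_kind,
            "calibration": self.calibration,
            "variant": "graph",
        }


class GraphCUSUM:
    """Graph-based change-point test on a similarity path.

    Parameters
    ----------
    data : array-like or SeriesData, optional
        n x q matrix from which distances are computed.
    dist : DistanceMatrix, optional
        Precomputed distances (alternative to ``data``).
    metric_kind : {"euclidean", "pseudo"}
        Euclidean detects mean and variance changes; pseudo (distance
        between row means) detects mean changes only.
    tau_kind, gamma
        Weight family and exponent (gamma in {1, 2}).
    """

    def __init__(self, data=None, dist: DistanceMatrix | None = None,
                 metric_kind: str = "euclidean", tau_kind: str = "center", gamma: int = 2):
        if (data is None) == (dist is None):
            raise InvalidInputError("provide exactly one of data or dist")
        self.dist = dist if dist is not None else distance_matrix(data, metric_kind)
        if self.dist.n < 3:
            raise InvalidInputError("graph test requires at least 3 time points")
        self.scheme = WeightScheme(self.dist.n, tau_kind, float(gamma))
        self.gamma = int(gamma)

    def fit(self, level: float = 0.05, calibration: str = "permutation",
            perm_reps: int = 2000, perm_seed: int = 0, **mc_kwargs) -> GraphTestResults:
        if not 0.0 < level < 1.0:
            raise InvalidInputError(f"level must lie in (0, 1), got {level}")
        path = shp_order(self.dist)
        curve = edge_count_curve(path)
        raw = graph_wc_statistic(curve, self.scheme)
        n = self.dist.n
        normed = normalize_graph_statistic(raw, n, self.gamma)
        w = compute_weights(self.scheme)
        dev = curve.perm_mean - curve.counts
        khat = int(np.argmax(dev / np.sqrt(w))) + 1
        if calibration == "asymptotic":
            sample = bridge.graph_limit_samples(self.scheme.tau_kind, self.gamma, **mc_kwargs)
            p = bridge.mc_pvalue(sample, normed)
            crit = bridge.mc_quantile(sample, 1.0 - level)
        elif calibration == "permutation":
            rng = np.random.default_rng(perm_seed)
            null = np.empty(perm_reps)
            for r in range(perm_reps):
                lab = rng.permutation(n)
                c = edge_count_curve(path, labels=lab)
                null[r] = normalize_graph_statistic(graph_wc_statistic(c, self.scheme),
                                                    n, self.gamma)
            null.sort()
            p = bridge.mc_pvalue(null, normed)
            crit = bridge.mc_quantile(null, 1.0 - level)
        else:
            raise InvalidInputError("calibration must be 'asymptotic' or 'permutation'")
        return GraphTestResults(
            statistic=normed, raw_statistic=raw, p_value=p, critical_value=crit,
            level=level, changepoint=khat, n=n, tau_kind=self.scheme.tau_kind,
            gamma=self.gamma, metric_kind=self.dist.metric_kind,
            calibration=calibration, path=path,
        )
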