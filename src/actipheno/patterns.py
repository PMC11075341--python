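"""Kernel k-means clustering of standardized 24-h curves into diurnal patterns.

The similarity between two day curves is a normalized Global Alignment Kernel
(GAK): the sum over all monotone alignments of products of a local Gaussian
kernel, made positive definite by the divisible transform k/(2-k) and
evaluated in log space for stability.  Clustering is Lloyd's algorithm in the
kernel-induced feature space, using Gram-matrix distances only (no explicit
centroids), followed by naming the five clusters against the diurnal
templates by maximum-total-correlation bijective matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import MalformedInputError, NamingConflictError
from .synthetic import PATTERN_NAMES, PatternTemplate

logger = logging.getLogger(__name__)

DEFAULT_MEMORY_CAP = 5000  # largest n for a dense Gram matrix
_SIGMA_SAMPLE_CURVES = 100
_SIGMA_SAMPLE_SEED = 0  # fixed: sigma resolution is deterministic by contract


@dataclass(frozen=True)
class KernelConfig:
    """Kernel choice and bandwidth for the day-curve Gram matrix."""

    kernel: str = "gak"
    sigma: float | str = "auto"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.kernel not in ("gak", "rbf"):
            raise MalformedInputError(f"unknown kernel {self.kernel!r}")
        if self.sigma != "auto" and not (isinstance(self.sigma, (int, float)) and self.sigma > 0):
            raise MalformedInputError("sigma must be positive or 'auto'")


@njit(cache=True)
def _log_gak(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """log of the unnormalized GAK between two equal-length series.

    Local kernel kappa(a,b) = exp(-(a-b)^2 / (2 sigma^2)); divisible form
    kappa/(2-kappa); alignment DP M[i,j] = k~(x_i,y_j) * (M[i-1,j-1] +
    M[i-1,j] + M[i,j-1]) accumulated in log space.
    """
    n = x.shape[0]
    m = y.shape[0]
    inv = 1.0 / (2.0 * sigma * sigma)
    neg_inf = -np.inf
    prev = np.full(m + 1, neg_inf)
    cur = np.full(m + 1, neg_inf)
    prev[0] = 0.0  # M[0,0] = 1
    for i in range(1, n + 1):
        cur[0] = neg_inf
        xi = x[i - 1]
        for j in range(1, m + 1):
            d = xi - y[j - 1]
            lk = -d * d * inv
            # log of divisible kernel: lk - log(2 - exp(lk)); exp(lk) <= 1
            ldk = lk - np.log(2.0 - np.exp(lk))
            a = prev[j - 1]
            b = prev[j]
            c = cur[j - 1]
            hi = max(a, max(b, c))
            if hi == neg_inf:
                cur[j] = neg_inf
            else:
                cur[j] = ldk + hi + np.log(
                    np.exp(a - hi) + np.exp(b - hi) + np.exp(c - hi)
                )
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _gak_gram_log(Z: np.ndarray, sigma: float) -> np.ndarray:
    n = Z.shape[0]
    out = np.empty((n, n))
    diag = np.empty(n)
    for i in range(n):
        diag[i] = _log_gak(Z[i], Z[i], sigma)
    for i in range(n):
        out[i, i] = diag[i]
        for j in range(i + 1, n):
            v = _log_gak(Z[i], Z[j], sigma)
            out[i, j] = v
            out[j, i] = v
    return out


def gak_similarity(x: np.ndarray, y: np.ndarray, sigma: float, normalize: bool = True) -> float:
    """Normalized GAK similarity in (0, 1]; K(x, x) = 1 when normalized."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise MalformedInputError("series must be 1-D and of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise MalformedInputError("series must be finite")
    if not sigma > 0:
        raise MalformedInputError("sigma must be positive")
    lxy = _log_gak(x, y, sigma)
    if not normalize:
        return float(np.exp(lxy))
    lxx = _log_gak(x, x, sigma)
    lyy = _log_gak(y, y, sigma)
    return float(np.exp(lxy - 0.5 * (lxx + lyy)))


def resolve_sigma(Z: np.ndarray, rule: str | float = "auto") -> float:
    """Bandwidth: median |a-b| over sampled point pairs, scaled by sqrt(T).

    At most 100 curves are sampled (fixed internal seed, so the result is
    deterministic); distances are taken over unordered distinct pairs of the
    pooled sample values.  A zero median falls back to the mean positive
    distance; identical values throughout make the bandwidth unresolvable.
    """
    if rule != "auto":
        if not (isinstance(rule, (int, float)) and rule > 0):
            raise MalformedInputError("sigma must be positive or 'auto'")
        return float(rule)
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise MalformedInputError("need at least two curves to resolve sigma")
    rng = np.random.default_rng(_SIGMA_SAMPLE_SEED)
    if Z.shape[0] > _SIGMA_SAMPLE_CURVES:
        Z = Z[rng.choice(Z.shape[0], _SIGMA_SAMPLE_CURVES, replace=False)]
    vals = np.sort(Z.ravel())
    diffs = np.abs(vals[:, None] - vals[None, :])
    dists = diffs[np.triu_indices(len(vals), k=1)]
    med = float(np.median(dists))
    if med == 0.0:
        pos = dists[dists > 0]
        if pos.size == 0:
            raise MalformedInputError("all values identical; cannot set bandwidth")
        med = float(pos.mean())
    return med * np.sqrt(Z.shape[1])


def compute_gram(
    Z: np.ndarray,
    cfg: KernelConfig = KernelConfig(),
    memory_cap: int = DEFAULT_MEMORY_CAP,
) -> np.ndarray:
    """Dense n x n similarity matrix over day curves.

    Refuses n beyond memory_cap (a full-scale cohort Gram is out of scope;
    subsample and assign held-out days to the nearest cluster instead).
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] == 0:
        raise MalformedInputError("Z must be a nonempty 2-D array of curves")
    if not np.all(np.isfinite(Z)):
        raise MalformedInputError("curves must be finite")
    n = Z.shape[0]
    if n > memory_cap:
        raise MalformedInputError(
            f"n={n} exceeds the Gram memory cap ({memory_cap}); "
            "subsample the days and assign the rest to the nearest cluster"
        )
    sigma = resolve_sigma(Z, cfg.sigma)
    logger.info("computing %s Gram: n=%d, sigma=%.4f", cfg.kernel, n, sigma)
    if cfg.kernel == "rbf":
        d2 = cdist(Z, Z, "sqeuclidean")
        K = np.exp(-d2 / (2.0 * sigma**2))
        # the RBF kernel is already unit-diagonal
        return K
    L = _gak_gram_log(Z, sigma)
    if cfg.normalize:
        d = np.diag(L)
        K = np.exp(L - 0.5 * (d[:, None] + d[None, :]))
        np.fill_diagonal(K, 1.0)
    else:
        K = np.exp(L)
    logger.info("Gram done: min=%.4g, max off-diag=%.4g", K.min(), np.max(K - np.eye(n)))
    return K


@dataclass
class ClusteringResult:
    """Hard assignment of days to clusters with the feature-space objective."""

    labels: np.ndarray
    inertia: float
    n_iter: int
    inertia_history: list[float]
    names: dict[int, str] | None = None

    def named_labels(self) -> np.ndarray:
        if self.names is None:
            raise MalformedInputError("clusters are unnamed")
        return np.array([self.names[int(c)] for c in self.labels])


def _cluster_distances(K: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """d^2(i, C) = K_ii - 2/|C| sum_{j in C} K_ij + 1/|C|^2 sum_{j,l in C} K_jl."""
    n = K.shape[0]
    Zmat = np.zeros((n, k))
    Zmat[np.arange(n), labels] = 1.0
    sizes = Zmat.sum(axis=0)
    sizes_safe = np.where(sizes > 0, sizes, 1.0)
    S = K @ Zmat  # n x k: sum_{j in C} K_ij
    within = (Zmat * S).sum(axis=0)  # sum_{j,l in C} K_jl
    d2 = (
        np.diag(K)[:, None]
        - 2.0 * S / sizes_safe[None, :]
        + (within / sizes_safe**2)[None, :]
    )
    d2[:, sizes == 0] = np.inf
    return d2


def _objective(K: np.ndarray, labels: np.ndarray, k: int) -> float:
    n = K.shape[0]
    total = float(np.trace(K))
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        if idx.size:
            total -= float(K[np.ix_(idx, idx)].sum()) / idx.size
    return total


def _lloyd_kernel(
    K: np.ndarray, init_labels: np.ndarray, k: int, max_iter: int
) -> tuple[np.ndarray, float, int, list[float]]:
    labels = init_labels.copy()
    history = [_objective(K, labels, k)]
    for it in range(1, max_iter + 1):
        d2 = _cluster_distances(K, labels, k)
        new = d2.argmin(axis=1)  # ties -> lowest cluster index
        # empty-cluster repair: reseed with the point farthest from its own cluster
        for c in range(k):
            if not np.any(new == c):
                own = d2[np.arange(len(new)), new]
                donor_ok = np.bincount(new, minlength=k)[new] > 1
                own = np.where(donor_ok, own, -np.inf)
                far = int(own.argmax())
                new[far] = c
        if np.array_equal(new, labels):
            history.append(_objective(K, labels, k))
            return labels, history[-1], it, history
        labels = new
        history.append(_objective(K, labels, k))
    return labels, history[-1], max_iter, history


def kernel_kmeans(
    K: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 100,
    init_labels: np.ndarray | None = None,
) -> ClusteringResult:
    """Lloyd's algorithm in feature space on a precomputed Gram matrix.

    Each restart seeds clusters from k random points (every day joins its
    nearest seed); the best restart by inertia wins.  Pass init_labels to fix
    the initialization (n_init is then ignored), e.g. to match an input-space
    run of Lloyd's under a linear kernel.
    """
    K = np.asarray(K, dtype=float)
    n = K.shape[0]
    if n == 0:
        raise MalformedInputError("empty Gram matrix")
    if k > n or k < 1:
        raise MalformedInputError(f"k={k} incompatible with n={n}")
    if init_labels is not None:
        labels, inertia, n_iter, hist = _lloyd_kernel(
            K, np.asarray(init_labels, dtype=np.int64), k, max_iter
        )
        return ClusteringResult(labels, inertia, n_iter, hist)
    rng = np.random.default_rng(seed)
    best: ClusteringResult | None = None
    diag = np.diag(K)
    for _ in range(n_init):
        seeds = rng.choice(n, size=k, replace=False)
        # assign each point to its nearest seed point in feature space
        d2 = diag[:, None] + diag[seeds][None, :] - 2.0 * K[:, seeds]
        init = d2.argmin(axis=1).astype(np.int64)
        init[seeds] = np.arange(k)  # each seed anchors its own cluster
        labels, inertia, n_iter, hist = _lloyd_kernel(K, init, k, max_iter)
        if best is None or inertia < best.inertia - 1e-12:
            best = ClusteringResult(labels, inertia, n_iter, hist)
    assert best is not None
    return best


def name_pattern_clusters(
    result: ClusteringResult,
    Z: np.ndarray,
    templates: dict[str, PatternTemplate],
) -> ClusteringResult:
    """Name the five clusters against the standardized templates.

    Each cluster's mean z-curve is correlated (Pearson) with every
    standardized template; names are assigned by the bijective matching that
    maximizes total correlation (Hungarian algorithm).
    """
    k = int(result.labels.max()) + 1
    if k != len(PATTERN_NAMES) or len(set(result.labels)) != len(PATTERN_NAMES):
        raise MalformedInputError("naming requires exactly 5 populated clusters")
    means = np.stack([Z[result.labels == c].mean(axis=0) for c in range(k)])
    tmpl = np.stack([templates[n].standardized() for n in PATTERN_NAMES])
    corr = np.corrcoef(np.vstack([means, tmpl]))[:k, k:]
    rows, cols = linear_sum_assignment(-corr)
    names = {int(r): PATTERN_NAMES[c] for r, c in zip(rows, cols)}
    if len(set(names.values())) != k:
        raise NamingConflictError("template matching produced duplicate names")
    return ClusteringResult(
        result.labels, result.inertia, result.n_iter, result.inertia_history, names
    )


def cluster_profiles(Z: np.ndarray, named_labels: np.ndarray) -> "pd.DataFrame":
    """Per-pattern mean and SD z-curves (the cluster-profile export)."""
    import pandas as pd

    rows = []
    for name in PATTERN_NAMES:
        sel = Z[named_labels == name]
        if len(sel) == 0:
            continue
        row = {"pattern_name": name, "n_days": len(sel)}
        row.update({f"h{h:02d}_mean": sel[:, h].mean() for h in range(Z.shape[1])})
        row.update({f"h{h:02d}_sd": sel[:, h].std() for h in range(Z.shape[1])})
        rows.append(row)
    return pd.DataFrame(rows)
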