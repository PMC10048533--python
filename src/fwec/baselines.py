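"""Reference clustering algorithms: K-Means, WK-Means and FCM.

These share the data model and the random-row center initialization of
the main algorithm so comparisons are not confounded by initialization.
WK-Means carries one global weight per feature (exponent ``beta``);
FCM carries a fuzzy membership matrix (fuzzifier ``m``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data import DataMatrix

logger = logging.getLogger(__name__)

VARIANTS = ("kmeans", "wkmeans", "fcm")


@dataclass
class BaselineConfig:
    k: int
    variant: str = "kmeans"
    beta: float = 2.0
    m: float = 2.0
    tol: float = 1e-5
    max_iter: int = 100
    restarts: int = 20
    seed: int = 0

    def validate(self, n_samples: int | None = None) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if n_samples is not None and self.k > n_samples:
            raise ValueError(f"k={self.k} exceeds the number of samples {n_samples}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.variant == "wkmeans" and not (self.beta > 1 or self.beta <= 0):
            raise ValueError("wkmeans requires beta > 1 or beta <= 0")
        if self.variant == "fcm" and not self.m > 1:
            raise ValueError("fcm requires fuzzifier m > 1")
        if self.tol <= 0 or self.max_iter < 1 or self.restarts < 1:
            raise ValueError("tol, max_iter and restarts must be positive")


@dataclass
class BaselineModel:
    """State of a fitted baseline; hard or fuzzy depending on the variant."""

    centers: np.ndarray
    objective_trace: np.ndarray
    hard_assign: np.ndarray | None = None  # one-hot N x K
    fuzzy_U: np.ndarray | None = None  # row-stochastic N x K
    global_weights: np.ndarray | None = None  # length M, sums to 1

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def hard_labels(self) -> np.ndarray:
        if self.hard_assign is not None:
            return np.argmax(self.hard_assign, axis=1)
        return np.argmax(self.fuzzy_U, axis=1)


def _init_centers(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(X.shape[0], size=k, replace=False)
    return X[idx].copy()


def _sq_dist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """(N, K) matrix of squared Euclidean distances."""
    return ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)


def _one_hot(assign: np.ndarray, k: int) -> np.ndarray:
    return np.eye(k)[assign]


def _fix_empty_clusters(X, C, assign, k):
    """Re-seed each empty cluster's center from the farthest point."""
    for j in range(k):
        if not np.any(assign == j):
            d = ((X - C[assign]) ** 2).sum(axis=1)
            far = int(np.argmax(d))
            logger.warning("empty cluster %d re-seeded from sample %d", j, far)
            C[j] = X[far]
            assign[far] = j
    return C, assign


# ---------------------------------------------------------------------------
# K-Means


def _kmeans_once(X, k, rng, tol, max_iter):
    n = X.shape[0]
    C = _init_centers(X, k, rng)
    assign = np.full(n, -1)
    trace = []
    for _ in range(max_iter):
        d2 = _sq_dist(X, C)
        new_assign = np.argmin(d2, axis=1)
        C, new_assign = _fix_empty_clusters(X, C.copy(), new_assign, k)
        for j in range(k):
            members = new_assign == j
            C[j] = X[members].mean(axis=0)
        obj = float(((X - C[new_assign]) ** 2).sum())
        trace.append(obj)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return BaselineModel(
        centers=C,
        objective_trace=np.asarray(trace),
        hard_assign=_one_hot(assign, k),
    )


# ---------------------------------------------------------------------------
# WK-Means


def _wkmeans_weights(disp: np.ndarray, beta: float) -> np.ndarray:
    """Global weights from per-feature dispersions, exponent 1/(beta-1)."""
    zero = disp <= 0
    if np.any(zero):
        logger.warning(
            "wkmeans: %d zero-dispersion feature(s) share all weight", int(zero.sum())
        )
        w = np.zeros_like(disp)
        w[zero] = 1.0 / zero.sum()
        return w
    ratio = disp[:, None] / disp[None, :]  # ratio[j, t] = D_j / D_t
    return 1.0 / (ratio ** (1.0 / (beta - 1.0))).sum(axis=1)


def _wkmeans_once(X, k, beta, rng, tol, max_iter):
    n, m = X.shape
    C = _init_centers(X, k, rng)
    w = np.full(m, 1.0 / m)
    assign = np.full(n, -1)
    trace = []
    for _ in range(max_iter):
        d2 = (w**beta)[None, None, :] * (X[:, None, :] - C[None, :, :]) ** 2
        new_assign = np.argmin(d2.sum(axis=2), axis=1)
        C, new_assign = _fix_empty_clusters(X, C.copy(), new_assign, k)
        for j in range(k):
            C[j] = X[new_assign == j].mean(axis=0)
        disp = ((X - C[new_assign]) ** 2).sum(axis=0)  # per-feature D_j
        w = _wkmeans_weights(disp, beta)
        obj = float(((w**beta)[None, :] * (X - C[new_assign]) ** 2).sum())
        trace.append(obj)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return BaselineModel(
        centers=C,
        objective_trace=np.asarray(trace),
        hard_assign=_one_hot(assign, k),
        global_weights=w,
    )


# ---------------------------------------------------------------------------
# FCM

_COINCIDENT_EPS = 1e-12


def fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Inverse-distance memberships with exponent 2/(m-1) on the distance ratio.

    A sample coinciding with a center receives membership 1 there
    (split evenly if it coincides with several).
    """
    n, k = d2.shape
    U = np.empty((n, k))
    coincident = d2 <= _COINCIDENT_EPS
    hit = coincident.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))  # (1/d2)^(1/(m-1)) == ratio exponent 2/(m-1)
        U = inv / inv.sum(axis=1, keepdims=True)
    if np.any(hit):
        U[hit] = coincident[hit] / coincident[hit].sum(axis=1, keepdims=True)
    return U


def _fcm_once(X, k, m, rng, tol, max_iter):
    C = _init_centers(X, k, rng)
    trace = []
    prev = np.inf
    U = None
    for _ in range(max_iter):
        d2 = _sq_dist(X, C)
        U = fcm_memberships(d2, m)
        Um = U**m
        C = (Um.T @ X) / Um.sum(axis=0)[:, None]
        obj = float((Um * _sq_dist(X, C)).sum())
        trace.append(obj)
        if abs(prev - obj) <= tol:
            break
        prev = obj
    return BaselineModel(
        centers=C,
        objective_trace=np.asarray(trace),
        fuzzy_U=U,
    )


# ---------------------------------------------------------------------------
# Restart wrappers


def _multi_restart(once, config: BaselineConfig, n_samples: int) -> BaselineModel:
    children = np.random.SeedSequence(config.seed).spawn(config.restarts)
    best = None
    for child in children:
        model = once(np.random.default_rng(child))
        if best is None or model.final_objective < best.final_objective:
            best = model
    return best


def kmeans_fit(data: DataMatrix, config: BaselineConfig) -> BaselineModel:
    """Lloyd's algorithm with random-row init and multi-restart."""
    config.validate(n_samples=data.n_samples)
    return _multi_restart(
        lambda rng: _kmeans_once(data.values, config.k, rng, config.tol, config.max_iter),
        config,
        data.n_samples,
    )


def wkmeans_fit(data: DataMatrix, config: BaselineConfig) -> BaselineModel:
    """K-Means with one global entropy-free weight per feature."""
    config.validate(n_samples=data.n_samples)
    if not (config.beta > 1 or config.beta <= 0):
        raise ValueError("beta must satisfy beta > 1 or beta <= 0")
    return _multi_restart(
        lambda rng: _wkmeans_once(
            data.values, config.k, config.beta, rng, config.tol, config.max_iter
        ),
        config,
        data.n_samples,
    )


def fcm_fit(data: DataMatrix, config: BaselineConfig) -> BaselineModel:
    """Fuzzy C-Means with fuzzifier ``m``."""
    config.validate(n_samples=data.n_samples)
    if config.m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    return _multi_restart(
        lambda rng: _fcm_once(
            data.values, config.k, config.m, rng, config.tol, config.max_iter
        ),
        config,
        data.n_samples,
    )


def baseline_fit(data: DataMatrix, config: BaselineConfig) -> BaselineModel:
    """Dispatch on ``config.variant``."""
    fitter = {"kmeans": kmeans_fit, "wkmeans": wkmeans_fit, "fcm": fcm_fit}[
        config.variant
    ]
    return fitter(data, config)
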