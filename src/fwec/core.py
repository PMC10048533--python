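"""Entropy-regularized, locally feature-weighted fuzzy clustering.

The model minimizes

    F(U, C, W) = sum_ijl u_ij w_jl d_l(x_il, c_jl)
                 + lam * sum_ij u_ij log u_ij
                 + gam * sum_jl w_jl log w_jl

subject to row-stochastic memberships U (N x K) and per-cluster feature
weights W (K x M), where the per-feature dissimilarity is either the
bounded kernel distance ``1 - exp(-delta_l (x - c)^2)`` or the squared
Euclidean distance.  Block-coordinate descent alternates three
closed-form (or fixed-point) updates; both entropy terms have exact
softmax minimizers, and the kernel center step is a
majorize-minimize step, so the objective trace is monotone
non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

from .data import DataMatrix, FeaturePrecision, compute_precision

logger = logging.getLogger(__name__)

DISTANCE_MODES = ("non_euclidean", "euclidean")

# Kernel-evaluation counter used by complexity tests: every bulk
# evaluation of the per-(sample, cluster, feature) distance/kernel tensor
# adds its element count here.
_op_counts = {"kernel_evals": 0}


def reset_kernel_eval_count() -> None:
    _op_counts["kernel_evals"] = 0


def kernel_eval_count() -> int:
    return _op_counts["kernel_evals"]


@dataclass
class ClusteringConfig:
    """Hyperparameters and run protocol for the clustering model.

    Defaults follow the reference protocol: ``lam=0.3``, ``gam=1.4``,
    ``tol=1e-5``, ``max_iter=100``, ``restarts=100``.
    """

    k: int
    lam: float = 0.3
    gam: float = 1.4
    tol: float = 1e-5
    max_iter: int = 100
    restarts: int = 100
    seed: int = 0
    distance_mode: str = "non_euclidean"

    def validate(self, n_samples: int | None = None) -> None:
        if self.k < 1:
            raise ValueError("k must be a positive integer")
        if n_samples is not None and self.k > n_samples:
            raise ValueError(f"k={self.k} exceeds the number of samples {n_samples}")
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if self.gam <= 0:
            raise ValueError("gam must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be a positive integer")
        if self.restarts < 1:
            raise ValueError("restarts must be a positive integer")
        if self.distance_mode not in DISTANCE_MODES:
            raise ValueError(f"distance_mode must be one of {DISTANCE_MODES}")

    def replace(self, **kwargs) -> "ClusteringConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class FwecModel:
    """Fitted state: memberships, feature weights, centers and trace."""

    U: np.ndarray
    W: np.ndarray
    C: np.ndarray
    precision: FeaturePrecision
    objective_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def final_objective(self) -> float:
        return float(self.objective_trace[-1])

    def hard_labels(self) -> np.ndarray:
        """Row-argmax of U; ties resolve to the lowest cluster index."""
        return np.argmax(self.U, axis=1)


@dataclass
class FitResult:
    """Best model across restarts plus bookkeeping."""

    model: FwecModel
    hard_labels: np.ndarray
    best_objective: float
    per_restart_objectives: np.ndarray


def pointwise_distance(x, c, delta_l, mode: str = "non_euclidean"):
    """Per-feature dissimilarity between a value and a center.

    ``non_euclidean`` mode returns ``1 - exp(-delta_l (x - c)^2)``, which
    lies in [0, 1) and saturates for distant points; ``euclidean`` mode
    returns the squared difference.
    """
    if mode not in DISTANCE_MODES:
        raise ValueError(f"unknown distance mode {mode!r}")
    diff2 = (np.asarray(x, dtype=float) - np.asarray(c, dtype=float)) ** 2
    if mode == "euclidean":
        return diff2
    return -np.expm1(-np.asarray(delta_l, dtype=float) * diff2)


def _distance_tensor(X, C, delta, mode):
    """(N, K, M) tensor of per-feature dissimilarities of samples vs centers."""
    diff2 = (X[:, None, :] - C[None, :, :]) ** 2
    _op_counts["kernel_evals"] += diff2.size
    if mode == "euclidean":
        return diff2
    return -np.expm1(-delta[None, None, :] * diff2)


def sample_cluster_dispersion(X, W, C, delta, mode: str = "non_euclidean"):
    """Weighted dissimilarity D[i, j] = sum_l W[j, l] * d_l(X[i, l], C[j, l])."""
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    C = np.asarray(C, dtype=float)
    if W.shape != C.shape:
        raise ValueError(f"W {W.shape} and C {C.shape} must have equal shapes")
    if W.shape[1] != X.shape[1]:
        raise ValueError(
            f"feature count mismatch: data has {X.shape[1]}, model has {W.shape[1]}"
        )
    d = _distance_tensor(X, C, np.asarray(delta, dtype=float), mode)
    return np.einsum("jl,ijl->ij", W, d)


def _entropy_softmax(neg_scores, scale):
    """Row-softmax of ``-neg_scores / scale``, shift-stabilized.

    Subtracting the per-row minimum score before exponentiation is
    algebraically a no-op but prevents underflow of entire rows for
    small ``scale``.  A tiny floor keeps every entry strictly positive.
    """
    a = -(neg_scores - neg_scores.min(axis=1, keepdims=True)) / scale
    p = np.exp(a)
    p = np.maximum(p, np.finfo(float).tiny)
    p /= p.sum(axis=1, keepdims=True)
    return p


def update_memberships(dispersion: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form membership update: u_ij ∝ exp(-D_ij / lam), rows sum to 1."""
    if lam <= 0:
        raise ValueError("lam must be > 0")
    return _entropy_softmax(np.asarray(dispersion, dtype=float), lam)


def update_weights(
    X, U, C, delta, gam: float, mode: str = "non_euclidean", d_tensor=None
) -> np.ndarray:
    """Closed-form feature-weight update.

    The per-(cluster, feature) dispersion is
    ``D'[j, l] = sum_i U[i, j] * d_l(X[i, l], C[j, l])`` and
    ``w_jl ∝ exp(-D'[j, l] / gam)`` with rows summing to 1.
    """
    if gam <= 0:
        raise ValueError("gam must be > 0")
    if d_tensor is None:
        d_tensor = _distance_tensor(
            np.asarray(X, dtype=float),
            np.asarray(C, dtype=float),
            np.asarray(delta, dtype=float),
            mode,
        )
    dp = np.einsum("ij,ijl->jl", np.asarray(U, dtype=float), d_tensor)
    return _entropy_softmax(dp, gam)


def cluster_feature_dispersion(X, U, C, delta, mode: str = "non_euclidean"):
    """D'[j, l] = sum_i U[i, j] * d_l(X[i, l], C[j, l]) (K x M)."""
    d = _distance_tensor(
        np.asarray(X, dtype=float),
        np.asarray(C, dtype=float),
        np.asarray(delta, dtype=float),
        mode,
    )
    return np.einsum("ij,ijl->jl", np.asarray(U, dtype=float), d)


_DEN_FLOOR = 1e-300


def update_centers(
    X, U, W, delta, C_prev, mode: str = "non_euclidean"
) -> np.ndarray:
    """One fixed-point (iteratively reweighted mean) center step.

    The stationary equation for a kernel center has the center inside the
    exponential; evaluating the kernel at the previous iterate yields

        c_jl = sum_i u_ij k_ijl x_il / sum_i u_ij k_ijl,
        k_ijl = exp(-delta_l (x_il - c_prev[j, l])^2).

    The w_jl and delta_l factors cancel between numerator and
    denominator.  Since ``1 - exp(-delta t)`` is concave in ``t``, this is
    a majorize-minimize step and cannot increase the objective.  In
    euclidean mode the exact minimizer (membership-weighted mean) is
    returned.
    """
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    C_prev = np.asarray(C_prev, dtype=float)
    if mode == "euclidean":
        den = U.sum(axis=0)
        return (U.T @ X) / den[:, None]
    delta = np.asarray(delta, dtype=float)
    diff2 = (X[:, None, :] - C_prev[None, :, :]) ** 2
    _op_counts["kernel_evals"] += diff2.size
    kern = np.exp(-delta[None, None, :] * diff2)
    den = np.einsum("ij,ijl->jl", U, kern)
    num = np.einsum("ij,ijl,il->jl", U, kern, X)
    dead = den <= _DEN_FLOOR
    if np.any(dead):
        logger.warning(
            "center update: %d entries lost all kernel mass; keeping previous",
            int(dead.sum()),
        )
    safe_den = np.where(dead, 1.0, den)
    return np.where(dead, C_prev, num / safe_den)


def objective(
    X, U, W, C, delta, lam: float, gam: float, mode: str = "non_euclidean"
) -> float:
    """Evaluate the full regularized objective (may be negative)."""
    X = np.asarray(X, dtype=float)
    U = np.asarray(U, dtype=float)
    W = np.asarray(W, dtype=float)
    d = _distance_tensor(X, np.asarray(C, dtype=float), np.asarray(delta, dtype=float), mode)
    dist = float(np.einsum("ij,jl,ijl->", U, W, d))
    # xlogy handles the 0*log(0)=0 convention (entries are positive anyway)
    ent_u = float(xlogy(U, U).sum())
    ent_w = float(xlogy(W, W).sum())
    return dist + lam * ent_u + gam * ent_w


def objective_of_model(data: DataMatrix, model: FwecModel, config: ClusteringConfig) -> float:
    """Objective of a fitted model on its data, under ``config``."""
    return objective(
        data.values,
        model.U,
        model.W,
        model.C,
        model.precision.delta,
        config.lam,
        config.gam,
        config.distance_mode,
    )


def fit_once(
    data: DataMatrix,
    config: ClusteringConfig,
    seed=None,
    callback=None,
) -> FwecModel:
    """Run the alternating-update loop from one random initialization.

    Centers start at K distinct data rows sampled without replacement;
    weights start uniform at 1/M.  Each sweep updates, in order, the
    membership matrix, the weight matrix and the center matrix, then
    recomputes the objective.  Iteration stops once the absolute
    objective change drops to ``config.tol`` or after
    ``config.max_iter`` sweeps.

    Parameters
    ----------
    seed : int, numpy Generator or SeedSequence, optional
        Source of randomness for the center initialization; defaults to
        ``config.seed``.
    callback : callable, optional
        Called after every sweep as ``callback(U, W, C, F)``; used by
        invariant tests to inspect intermediate iterates.
    """
    config.validate(n_samples=data.n_samples)
    X = data.values
    n, m = X.shape
    k = config.k
    precision = compute_precision(data)
    delta = precision.delta
    mode = config.distance_mode

    rng = np.random.default_rng(config.seed if seed is None else seed)
    centers_idx = rng.choice(n, size=k, replace=False)
    C = X[centers_idx].copy()
    W = np.full((k, m), 1.0 / m)
    U = np.full((n, k), 1.0 / k)

    trace: list[float] = []
    converged = False
    for t in range(config.max_iter):
        d = _distance_tensor(X, C, delta, mode)
        D = np.einsum("jl,ijl->ij", W, d)
        U = update_memberships(D, config.lam)
        W = update_weights(X, U, C, delta, config.gam, mode, d_tensor=d)
        C = update_centers(X, U, W, delta, C, mode)
        f = objective(X, U, W, C, delta, config.lam, config.gam, mode)
        if not np.isfinite(f):
            raise FloatingPointError(f"objective became non-finite at iteration {t}")
        trace.append(f)
        if callback is not None:
            callback(U, W, C, f)
        if t > 0 and abs(trace[-2] - f) <= config.tol:
            converged = True
            break

    return FwecModel(
        U=U,
        W=W,
        C=C,
        precision=precision,
        objective_trace=np.asarray(trace),
        n_iter=len(trace),
        converged=converged,
    )


def fit(data: DataMatrix, config: ClusteringConfig) -> FitResult:
    """Multi-restart fit keeping the lowest-objective model.

    Restart seeds are spawned deterministically from ``config.seed``, so
    a run is bit-reproducible for a fixed config.
    """
    config.validate(n_samples=data.n_samples)
    children = np.random.SeedSequence(config.seed).spawn(config.restarts)
    best: FwecModel | None = None
    objectives = np.empty(config.restarts)
    errors: list[Exception] = []
    for r, child in enumerate(children):
        try:
            model = fit_once(data, config, seed=child)
        except FloatingPointError as exc:  # keep going; other restarts may succeed
            logger.warning("restart %d failed: %s", r, exc)
            errors.append(exc)
            objectives[r] = np.inf
            continue
        objectives[r] = model.final_objective
        if best is None or model.final_objective < best.final_objective:
            best = model
    if best is None:
        raise RuntimeError(f"all {config.restarts} restarts failed: {errors[:3]}")
    return FitResult(
        model=best,
        hard_labels=best.hard_labels(),
        best_objective=float(np.min(objectives)),
        per_restart_objectives=objectives,
    )
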