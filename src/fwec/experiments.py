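"""Desk-scale experiment drivers: sensitivity sweeps, distance-mode
comparison and the noise-feature robustness experiment.

Every driver is deterministic given (data/spec, config): all randomness
flows from ``config.seed`` through spawned substreams, and result
payloads carry no timestamps, so re-running yields identical JSON.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import core, metrics
from .data import DataMatrix
from .synthetic import SyntheticSpec, add_noise_features, make_blobs

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(np.round(np.arange(0.1, 2.01, 0.1), 10))


@dataclass
class SweepResult:
    swept_parameter: str
    grid: tuple[float, ...]
    fixed_parameters: dict
    rows: list[dict]

    def to_payload(self) -> dict:
        return asdict(self)


def _clamp_grid(grid) -> tuple[float, ...]:
    """Replace non-positive grid points with the smallest positive step."""
    grid = [float(g) for g in grid]
    positive = sorted(g for g in grid if g > 0)
    if not positive:
        raise ValueError("grid must contain at least one positive value")
    step = positive[0]
    clamped = []
    for g in grid:
        if g <= 0:
            logger.warning("grid point %g clamped to %g (must be positive)", g, step)
            g = step
        clamped.append(g)
    out = tuple(dict.fromkeys(clamped))  # drop duplicates, keep order
    if any(b <= a for a, b in zip(out, out[1:])):
        raise ValueError("grid must be strictly increasing after clamping")
    return out


def _scores(result: core.FitResult, data: DataMatrix) -> dict:
    if data.labels is None:
        return {"acc": None, "ri": None, "nmi": None}
    m = metrics.evaluate(result.hard_labels, data.labels)
    return {"acc": m.acc, "ri": m.ri, "nmi": m.nmi}


def sensitivity_sweep(
    data: DataMatrix,
    config: core.ClusteringConfig,
    which: str,
    grid=None,
) -> SweepResult:
    """Refit at every grid value of ``lam`` or ``gam``, sharing seeds.

    The default grid is 0.1 to 2.0 in steps of 0.1 (grid points of 0 are
    clamped to the first positive step).
    """
    if which not in ("lam", "gam"):
        raise ValueError("which must be 'lam' or 'gam'")
    grid = _clamp_grid(DEFAULT_GRID if grid is None else grid)
    rows = []
    for value in grid:
        cfg = config.replace(**{which: value})
        try:
            result = core.fit(data, cfg)
        except Exception as exc:
            raise RuntimeError(f"fit failed at {which}={value}") from exc
        rows.append(
            {
                which: value,
                **_scores(result, data),
                "best_objective": result.best_objective,
                "n_restarts": cfg.restarts,
            }
        )
    fixed = {
        f: getattr(config, f)
        for f in ("k", "lam", "gam", "tol", "max_iter", "restarts", "seed", "distance_mode")
        if f != which
    }
    return SweepResult(
        swept_parameter=which, grid=grid, fixed_parameters=fixed, rows=rows
    )


def distance_comparison(data: DataMatrix, config: core.ClusteringConfig) -> dict:
    """Identical multi-restart runs in both distance modes.

    Per mode, every restart's model is scored against the labels (when
    present) and the mean/variance of ACC across restarts is reported,
    along with the score of the best-objective restart.  Restart seeds
    are shared between the two modes.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.restarts)
    report: dict = {"modes": {}}
    for mode in core.DISTANCE_MODES:
        cfg = config.replace(distance_mode=mode)
        cfg.validate(n_samples=data.n_samples)
        accs, objectives, models = [], [], []
        for child in children:
            model = core.fit_once(data, cfg, seed=child)
            objectives.append(model.final_objective)
            models.append(model)
            if data.labels is not None:
                accs.append(metrics.accuracy(model.hard_labels(), data.labels))
        best_idx = int(np.argmin(objectives))
        entry = {
            "best_objective": float(objectives[best_idx]),
            "per_restart_objectives": [float(o) for o in objectives],
        }
        if accs:
            entry.update(
                {
                    "acc_mean": float(np.mean(accs)),
                    "acc_var": float(np.var(accs)),
                    "acc_best_objective_model": float(accs[best_idx]),
                    "per_restart_acc": [float(a) for a in accs],
                }
            )
        report["modes"][mode] = entry
    return report


def noise_experiment(
    spec: SyntheticSpec,
    config: core.ClusteringConfig,
    m_noise: int | None = None,
) -> dict:
    """Fit on clean vs noise-augmented versions of the same blob matrix.

    Reports the ACC of both arms and, for the noisy arm, each cluster's
    mean feature weight on informative vs noise columns.
    """
    clean_spec = SyntheticSpec(
        n_per_cluster=spec.n_per_cluster,
        m_informative=spec.m_informative,
        m_noise=0,
        centers=spec.centers,
        separation=spec.separation,
        sigma=spec.sigma,
        noise_low=spec.noise_low,
        noise_high=spec.noise_high,
        seed=spec.seed,
    )
    m_noise = spec.m_noise if m_noise is None else m_noise
    clean = make_blobs(clean_spec)
    noisy = add_noise_features(
        clean,
        m_noise,
        low=spec.noise_low,
        high=spec.noise_high,
        seed=np.random.SeedSequence(spec.seed).spawn(1)[0],
    )

    res_clean = core.fit(clean, config)
    res_noisy = core.fit(noisy, config)

    m_inf = spec.m_informative
    W = res_noisy.model.W
    informative_w = W[:, :m_inf].mean(axis=1)
    noise_w = (
        W[:, m_inf:].mean(axis=1) if m_noise > 0 else np.full(W.shape[0], np.nan)
    )
    payload = {
        "m_informative": m_inf,
        "m_noise": m_noise,
        "acc_clean": metrics.accuracy(res_clean.hard_labels, clean.labels),
        "acc_noisy": metrics.accuracy(res_noisy.hard_labels, noisy.labels),
        "mean_weight_informative_per_cluster": informative_w.tolist(),
        "mean_weight_noise_per_cluster": noise_w.tolist(),
        "weights_noisy": W.tolist(),
    }
    payload["acc_change"] = abs(payload["acc_clean"] - payload["acc_noisy"])
    return payload
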