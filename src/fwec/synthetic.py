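"""Seeded generators for Gaussian-blob benchmarks with uniform noise features.

Informative columns are drawn from spherical Gaussians around per-cluster
centers; noise columns are i.i.d. uniform.  Everything is deterministic
given the seed, so tests and experiments never need stored fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix


@dataclass
class SyntheticSpec:
    """Recipe for a blob dataset.

    When ``centers`` is omitted, cluster j is placed at
    ``separation * sigma * j`` in every informative coordinate, so each
    informative feature on its own separates adjacent clusters by
    ``separation`` component standard deviations.
    """

    n_per_cluster: tuple[int, ...]
    m_informative: int
    m_noise: int = 0
    centers: np.ndarray | None = None
    separation: float = 6.0
    sigma: float = 1.0
    noise_low: float = 0.0
    noise_high: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.n_per_cluster = tuple(int(n) for n in self.n_per_cluster)
        if len(self.n_per_cluster) == 0 or any(n < 1 for n in self.n_per_cluster):
            raise ValueError("n_per_cluster must be a non-empty tuple of positives")
        if self.m_informative < 1:
            raise ValueError("m_informative must be >= 1")
        if self.m_noise < 0:
            raise ValueError("m_noise must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.noise_high <= self.noise_low:
            raise ValueError("noise_high must exceed noise_low")
        if self.centers is not None:
            self.centers = np.asarray(self.centers, dtype=float)
            if self.centers.shape != (self.k, self.m_informative):
                raise ValueError(
                    f"centers must have shape {(self.k, self.m_informative)}"
                )

    @property
    def k(self) -> int:
        return len(self.n_per_cluster)

    def resolved_centers(self) -> np.ndarray:
        if self.centers is not None:
            return self.centers
        scale = self.separation * self.sigma
        steps = scale * np.arange(self.k, dtype=float)
        return np.tile(steps[:, None], (1, self.m_informative))


def make_blobs(spec: SyntheticSpec) -> DataMatrix:
    """Generate the blob matrix (with labels) described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    centers = spec.resolved_centers()
    rows = []
    labels = []
    for j, n_j in enumerate(spec.n_per_cluster):
        rows.append(centers[j] + spec.sigma * rng.standard_normal((n_j, spec.m_informative)))
        labels.append(np.full(n_j, j))
    values = np.vstack(rows)
    data = DataMatrix(values=values, labels=np.concatenate(labels))
    if spec.m_noise > 0:
        # derive the noise seed from the spec seed so the whole matrix is
        # reproducible from a single integer
        data = add_noise_features(
            data,
            spec.m_noise,
            low=spec.noise_low,
            high=spec.noise_high,
            seed=np.random.SeedSequence(spec.seed).spawn(1)[0],
        )
    return data


def add_noise_features(
    data: DataMatrix,
    m_noise: int,
    low: float = 0.0,
    high: float = 1.0,
    seed=0,
) -> DataMatrix:
    """Append ``m_noise`` i.i.d. uniform(low, high) columns; labels untouched."""
    if m_noise < 0:
        raise ValueError("m_noise must be >= 0")
    if m_noise == 0:
        return data.with_values(data.values.copy())
    if high <= low:
        raise ValueError("high must exceed low")
    rng = np.random.default_rng(seed)
    noise = rng.uniform(low, high, size=(data.n_samples, m_noise))
    return data.with_values(np.hstack([data.values, noise]))
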