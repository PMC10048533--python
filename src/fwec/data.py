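"""Data containers and per-feature precision statistics.

The clustering stack operates on plain numeric matrices with samples as
rows and features as columns.  :class:`DataMatrix` wraps such a matrix
together with optional integer ground-truth labels (used for evaluation
only, never during fitting).  :func:`compute_precision` derives the
per-feature inverse-variance scale parameters that make the bounded
kernel distance scale-free per feature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Relative variance threshold below which a feature is treated as constant.
DEGENERATE_VAR_RTOL = 1e-12


@dataclass
class DataMatrix:
    """An N x M numeric matrix plus optional ground-truth labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        The data; every entry must be finite.
    labels : ndarray of shape (n_samples,), optional
        Integer ground-truth labels, for evaluation only.
    """

    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one row and one column")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix entries must all be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError(
                    f"labels must have length {n}, got shape {self.labels.shape}"
                )
            if self.labels.size and np.unique(self.labels).size < 1:
                raise ValueError("labels must contain at least one distinct value")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "DataMatrix":
        """Return a copy holding ``values`` but the same labels."""
        labels = None if self.labels is None else self.labels.copy()
        return DataMatrix(values=values, labels=labels)


@dataclass
class FeaturePrecision:
    """Per-feature scale parameters: inverse population variances.

    ``delta[l]`` is ``1 / var[l]`` for informative features and 0 for
    degenerate (near-constant) features, so that a constant column
    contributes nothing to the kernel distance.
    """

    delta: np.ndarray
    mean: np.ndarray
    var: np.ndarray
    degenerate: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if not (self.delta.shape == self.mean.shape == self.var.shape):
            raise ValueError("delta, mean and var must share a common length")
        if np.any(self.delta < 0) or not np.all(np.isfinite(self.delta)):
            raise ValueError("delta entries must be finite and non-negative")


def compute_precision(data: DataMatrix) -> FeaturePrecision:
    """Compute per-feature means, population variances and precisions.

    The precision of feature ``l`` is the inverse of its population
    variance (divisor N).  Features whose variance is (numerically) zero
    are flagged as degenerate and receive ``delta = 0`` so their distance
    contribution vanishes instead of dividing by zero.
    """
    x = data.values
    mean = x.mean(axis=0)
    var = x.var(axis=0)  # population variance, divisor N
    degenerate = var <= DEGENERATE_VAR_RTOL * np.maximum(1.0, mean**2)
    if np.any(degenerate):
        logger.warning(
            "%d feature(s) have (near-)zero variance; their distance "
            "contribution is set to zero: columns %s",
            int(degenerate.sum()),
            np.nonzero(degenerate)[0].tolist(),
        )
    delta = np.zeros_like(var)
    np.divide(1.0, var, out=delta, where=~degenerate)
    return FeaturePrecision(delta=delta, mean=mean, var=var, degenerate=degenerate)


def load_csv(
    path,
    label_col: str | int | None = None,
    header: bool = True,
    delimiter: str = ",",
) -> DataMatrix:
    """Read a delimited numeric matrix, optionally splitting off a label column.

    Parameters
    ----------
    path : str or file-like
        CSV/TSV file with samples as rows.
    label_col : str or int, optional
        Column name (requires a header) or 0-based position holding
        integer ground-truth labels.
    header : bool
        Whether the first row is a header.
    delimiter : str
        Field separator.
    """
    df = pd.read_csv(path, header=0 if header else None, sep=delimiter)
    labels = None
    if label_col is not None:
        if isinstance(label_col, str):
            if label_col not in df.columns:
                raise ValueError(f"label column {label_col!r} not found")
            labels = df.pop(label_col).to_numpy()
        else:
            labels = df.iloc[:, label_col].to_numpy()
            df = df.drop(columns=df.columns[label_col])
        codes, _ = pd.factorize(labels)
        labels = codes
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values are not supported")
    return DataMatrix(values=values, labels=labels)


def save_labels_csv(path, labels: np.ndarray, column: str = "label") -> None:
    """Write a single-column CSV of hard labels."""
    pd.DataFrame({column: np.asarray(labels)}).to_csv(path, index=False)
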