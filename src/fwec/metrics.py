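"""External clustering evaluation: accuracy, Rand index, NMI.

All three scores are invariant to permutations of the predicted cluster
ids.  Accuracy maps predicted clusters to true classes with an optimal
one-to-one assignment (maximum-weight bipartite matching on the
contingency table); a majority-vote variant is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import xlogy


@dataclass
class PartitionMetrics:
    """ACC / RI / NMI for a (predicted, true) label pair."""

    acc: float
    ri: float
    nmi: float
    contingency: np.ndarray
    mapping: dict[int, int]


def _check_pair(pred, true) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.shape != true.shape:
        raise ValueError(
            f"label vectors differ in length: {pred.size} vs {true.size}"
        )
    if pred.size < 1:
        raise ValueError("label vectors must be non-empty")
    return pred, true


def contingency_table(pred, true) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Counts matrix (predicted clusters x true classes) plus id arrays."""
    pred, true = _check_pair(pred, true)
    pred_ids, pred_codes = np.unique(pred, return_inverse=True)
    true_ids, true_codes = np.unique(true, return_inverse=True)
    table = np.zeros((pred_ids.size, true_ids.size), dtype=np.int64)
    np.add.at(table, (pred_codes, true_codes), 1)
    return table, pred_ids, true_ids


def accuracy(pred, true, mapping: str = "optimal") -> float:
    """Fraction correct under a cluster-to-class mapping.

    ``mapping="optimal"`` (default) uses the best one-to-one assignment;
    when cluster and class counts differ, unmatched clusters contribute
    zero correct.  ``mapping="majority"`` lets each cluster vote for its
    most frequent class (not one-to-one).
    """
    table, _, _ = contingency_table(pred, true)
    n = table.sum()
    if mapping == "optimal":
        rows, cols = linear_sum_assignment(table, maximize=True)
        correct = table[rows, cols].sum()
    elif mapping == "majority":
        correct = table.max(axis=1).sum()
    else:
        raise ValueError(f"unknown mapping {mapping!r}")
    return float(correct / n)


def cluster_class_mapping(pred, true) -> dict[int, int]:
    """The optimal one-to-one cluster -> class assignment used by ACC."""
    table, pred_ids, true_ids = contingency_table(pred, true)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return {int(pred_ids[r]): int(true_ids[c]) for r, c in zip(rows, cols)}


def rand_index(pred, true) -> float:
    """Fraction of unordered sample pairs on which the partitions agree."""
    pred, true = _check_pair(pred, true)
    n = pred.size
    if n < 2:
        raise ValueError("rand index requires at least 2 samples")
    table, _, _ = contingency_table(pred, true)
    table = table.astype(float)

    def pairs(x):
        return (x * (x - 1.0) / 2.0).sum()

    total = n * (n - 1.0) / 2.0
    together_both = pairs(table)  # same cluster and same class
    together_pred = pairs(table.sum(axis=1))
    together_true = pairs(table.sum(axis=0))
    # agreements = together in both + apart in both
    apart_both = total - together_pred - together_true + together_both
    return float((together_both + apart_both) / total)


def nmi(pred, true) -> float:
    """Mutual information normalized by sqrt(H(pred) * H(true)), natural log.

    If either marginal entropy is zero the score is 0, except when both
    partitions are the identical single-cluster partition, which scores 1.
    """
    table, _, _ = contingency_table(pred, true)
    n = table.sum()
    p = table / n
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    h_pred = float(-xlogy(pi, pi).sum())
    h_true = float(-xlogy(pj, pj).sum())
    if h_pred <= 0.0 or h_true <= 0.0:
        return 1.0 if (h_pred <= 0.0 and h_true <= 0.0) else 0.0
    outer = pi[:, None] * pj[None, :]
    mask = p > 0
    mi = float((p[mask] * np.log(p[mask] / outer[mask])).sum())
    return float(mi / np.sqrt(h_pred * h_true))


def evaluate(pred, true) -> PartitionMetrics:
    """All three scores plus the contingency table and the ACC mapping."""
    table, _, _ = contingency_table(pred, true)
    return PartitionMetrics(
        acc=accuracy(pred, true),
        ri=rand_index(pred, true),
        nmi=nmi(pred, true),
        contingency=table,
        mapping=cluster_class_mapping(pred, true),
    )
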