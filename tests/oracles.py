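"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is deliberately scalar-loop / enumeration based and never
calls the implementation under test.
"""

import itertools
import math

import numpy as np


def pointwise_oracle(x, c, delta_l, mode):
    if mode == "euclidean":
        return (x - c) ** 2
    return 1.0 - math.exp(-delta_l * (x - c) ** 2)


def dispersion_oracle(X, W, C, delta, mode="non_euclidean"):
    n, m = X.shape
    k = C.shape[0]
    D = np.zeros((n, k))
    for i in range(n):
        for j in range(k):
            for l in range(m):
                D[i, j] += W[j, l] * pointwise_oracle(X[i, l], C[j, l], delta[l], mode)
    return D


def weight_dispersion_oracle(X, U, C, delta, mode="non_euclidean"):
    n, m = X.shape
    k = C.shape[0]
    Dp = np.zeros((k, m))
    for j in range(k):
        for l in range(m):
            for i in range(n):
                Dp[j, l] += U[i, j] * pointwise_oracle(X[i, l], C[j, l], delta[l], mode)
    return Dp


def objective_oracle(X, U, W, C, delta, lam, gam, mode="non_euclidean"):
    n, m = X.shape
    k = C.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(k):
            for l in range(m):
                total += (
                    U[i, j]
                    * W[j, l]
                    * pointwise_oracle(X[i, l], C[j, l], delta[l], mode)
                )
    for i in range(n):
        for j in range(k):
            if U[i, j] > 0:
                total += lam * U[i, j] * math.log(U[i, j])
    for j in range(k):
        for l in range(m):
            if W[j, l] > 0:
                total += gam * W[j, l] * math.log(W[j, l])
    return total


def acc_oracle(pred, true):
    """Best fraction correct over all injective cluster -> class mappings."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    clusters = sorted(set(pred.tolist()))
    classes = sorted(set(true.tolist()))
    best = 0
    if len(clusters) <= len(classes):
        for perm in itertools.permutations(classes, len(clusters)):
            mapping = dict(zip(clusters, perm))
            best = max(best, sum(mapping[p] == t for p, t in zip(pred, true)))
    else:
        for perm in itertools.permutations(clusters, len(classes)):
            mapping = dict(zip(perm, classes))
            best = max(
                best,
                sum(mapping.get(p) == t for p, t in zip(pred, true)),
            )
    return best / pred.size


def ri_oracle(pred, true):
    """Pair-enumeration Rand index, O(N^2)."""
    n = len(pred)
    agree = 0
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_pred = pred[i] == pred[j]
            same_true = true[i] == true[j]
            agree += same_pred == same_true
            total += 1
    return agree / total


def nmi_oracle(pred, true):
    """Plug-in NMI from an explicitly built contingency table."""
    pred = list(pred)
    true = list(true)
    n = len(pred)
    clusters = sorted(set(pred))
    classes = sorted(set(true))
    joint = {}
    for p, t in zip(pred, true):
        joint[(p, t)] = joint.get((p, t), 0) + 1

    def entropy(labels, ids):
        h = 0.0
        for v in ids:
            p = labels.count(v) / n
            if p > 0:
                h -= p * math.log(p)
        return h

    h_pred = entropy(pred, clusters)
    h_true = entropy(true, classes)
    if h_pred <= 0 or h_true <= 0:
        return 1.0 if (h_pred <= 0 and h_true <= 0) else 0.0
    mi = 0.0
    for (p, t), c in joint.items():
        pij = c / n
        pi = pred.count(p) / n
        pj = true.count(t) / n
        mi += pij * math.log(pij / (pi * pj))
    return mi / math.sqrt(h_pred * h_true)


def kmeans_exhaustive(X, k):
    """Global optimum of the k-means objective by assignment enumeration."""
    n = X.shape[0]
    best = math.inf
    for assign in itertools.product(range(k), repeat=n):
        assign = np.asarray(assign)
        if len(set(assign.tolist())) < k:
            continue
        obj = 0.0
        for j in range(k):
            members = X[assign == j]
            obj += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, obj)
    return best
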