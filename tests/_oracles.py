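"""Independent reference implementations used only to check the package.

Everything here is written as plain, slow, textbook code — loops, explicit
scatter matrices, full enumeration — deliberately avoiding the package's own
vectorised implementations so the two routes stay independent.
"""

from __future__ import annotations

import math

import numpy as np


def lloyd_oracle(X, k, init_assignments, max_iter=200):
    """Textbook Lloyd's algorithm with pure-python loops.

    Same contract as the package engine: centroid update (cluster mean), then
    nearest-centroid reassignment, until the assignment is a fixed point; an
    emptied cluster is re-seeded with the point farthest from its own
    centroid. Returns (assignments, centroids, objective).
    """
    X = [list(map(float, row)) for row in np.asarray(X)]
    n, d = len(X), len(X[0])
    assign = [int(a) for a in init_assignments]
    centroids = [[0.0] * d for _ in range(k)]

    def dist2(p, q):
        return sum((pi - qi) ** 2 for pi, qi in zip(p, q))

    for _ in range(max_iter):
        for c in range(k):
            members = [i for i in range(n) if assign[i] == c]
            if members:
                for j in range(d):
                    centroids[c][j] = sum(X[i][j] for i in members) / len(members)
            else:
                far = max(range(n), key=lambda i: dist2(X[i], centroids[assign[i]]))
                centroids[c] = list(X[far])
                assign[far] = c
        new_assign = [
            min(range(k), key=lambda c: dist2(X[i], centroids[c])) for i in range(n)
        ]
        if new_assign == assign:
            break
        assign = new_assign
    obj = sum(dist2(X[i], centroids[assign[i]]) for i in range(n))
    return assign, centroids, obj


def calinski_harabasz_oracle(X, labels):
    """CH index from the full between/within scatter matrices (traces)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n, d = X.shape
    uniq = sorted(set(labels.tolist()))
    k = len(uniq)
    grand = X.mean(axis=0)
    B = np.zeros((d, d))
    W = np.zeros((d, d))
    for c in uniq:
        members = X[labels == c]
        mu = members.mean(axis=0)
        diff = (mu - grand)[:, None]
        B += len(members) * (diff @ diff.T)
        for row in members:
            r = (row - mu)[:, None]
            W += r @ r.T
    tr_w = np.trace(W)
    if tr_w == 0:
        return math.inf
    return (np.trace(B) / (k - 1)) / (tr_w / (n - k))


def fisher_exact_enum(a, b, c, d):
    """Two-sided Fisher p by full enumeration over the margin class.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    (probability-ordering definition, with a small relative tolerance for
    floating-point ties).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_comb(nn, kk):
        return math.lgamma(nn + 1) - math.lgamma(kk + 1) - math.lgamma(nn - kk + 1)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = log_comb(n, c1)
    probs = {}
    for x in range(lo, hi + 1):
        probs[x] = math.exp(log_comb(r1, x) + log_comb(r2, c1 - x) - denom)
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def bh_fdr_oracle(pvals):
    """Benjamini-Hochberg step-up by direct arithmetic."""
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def pearson_chi2_oracle(counts):
    """Sum of (O-E)^2/E over all cells, explicit loops."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    stat = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            e = counts[i].sum() * counts[:, j].sum() / total
            stat += (counts[i, j] - e) ** 2 / e
    return stat


def adjusted_rand_index(labels_a, labels_b):
    """Chance-corrected agreement between two partitions (pair-counting)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    cats_a = {v: i for i, v in enumerate(sorted(set(a.tolist())))}
    cats_b = {v: i for i, v in enumerate(sorted(set(b.tolist())))}
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    for x, y in zip(a, b):
        table[cats_a[x], cats_b[y]] += 1

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = sum(comb2(int(v)) for v in table.ravel())
    sum_i = sum(comb2(int(v)) for v in table.sum(axis=1))
    sum_j = sum(comb2(int(v)) for v in table.sum(axis=0))
    expected = sum_i * sum_j / comb2(n)
    max_index = (sum_i + sum_j) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
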