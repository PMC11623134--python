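"""Independent brute-force oracles used by the tests.

Everything here is written from the definitions alone (plain loops, explicit
set enumeration) and never calls into the package's split machinery, so it
can serve as a reference to check that machinery against.
"""

from __future__ import annotations

import itertools

import numpy as np


def gini(counts) -> float:
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    p = counts / n
    return 1.0 - float((p * p).sum())


def split_decrease(y_left, y_right, n_classes: int) -> float:
    """Gini(parent) − child-weighted Gini, from raw label-code vectors."""
    cl = np.bincount(y_left, minlength=n_classes)
    cr = np.bincount(y_right, minlength=n_classes)
    n = len(y_left) + len(y_right)
    parent = gini(cl + cr)
    return (
        parent
        - (len(y_left) / n) * gini(cl)
        - (len(y_right) / n) * gini(cr)
    )


def best_bipartition_decrease(x, y, n_classes: int = 2) -> float:
    """Exhaustive best Gini decrease over all 2^(k-1)-1 level bipartitions."""
    x = np.asarray(x, dtype=object)
    y = np.asarray(y)
    levels = sorted(set(x.tolist()))
    k = len(levels)
    best = 0.0
    for r in range(1, k):
        for subset in itertools.combinations(levels, r):
            mask = np.isin(x, subset)
            if mask.all() or not mask.any():
                continue
            best = max(best, split_decrease(y[mask], y[~mask], n_classes))
    return best


def best_threshold_decrease(x, y, n_classes: int) -> tuple[float, float] | None:
    """Exhaustive best (decrease, threshold) over midpoints of one column."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    vals = np.unique(x)
    if vals.size < 2:
        return None
    best = None
    for a, b in zip(vals[:-1], vals[1:]):
        thr = (a + b) / 2.0
        left = x <= thr
        dec = split_decrease(y[left], y[~left], n_classes)
        if best is None or dec > best[0]:
            best = (dec, thr)
    return best


def best_split_exhaustive(X, y, n_classes: int):
    """Exhaustive argmax over every (variable, threshold) pair.

    Ties break to the lower variable index then the smaller threshold,
    matching the documented contract.
    """
    X = np.asarray(X, dtype=float)
    best = None
    for j in range(X.shape[1]):
        res = best_threshold_decrease(X[:, j], y, n_classes)
        if res is None:
            continue
        dec, thr = res
        if best is None or dec > best[0] + 1e-15:
            best = (dec, j, thr)
    return best


def pca_ordering_oracle(levels, profiles, weights):
    """Level ordering from an explicit dense eigendecomposition.

    Plain-loop weighted covariance of the class-probability profiles, leading
    eigenvector with its first nonzero coordinate made positive, levels
    sorted by centered projection with lexicographic tie-break.
    """
    P = np.asarray(profiles, dtype=float)
    w = np.asarray(weights, dtype=float)
    C = P.shape[1]
    pbar = np.zeros(C)
    for i in range(len(levels)):
        pbar += w[i] * P[i]
    cov = np.zeros((C, C))
    for i in range(len(levels)):
        d = P[i] - pbar
        cov += w[i] * np.outer(d, d)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, int(np.argmax(vals))]
    for c in range(C):
        if abs(v[c]) > 1e-12:
            if v[c] < 0:
                v = -v
            break
    scores = [(float((P[i] - pbar) @ v), levels[i]) for i in range(len(levels))]
    return [lev for _, lev in sorted(scores)]
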