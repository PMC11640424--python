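"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration or exhaustive
search, deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def interp_two_point(x: float, xs: np.ndarray, ys: np.ndarray) -> float:
    """Piecewise-linear interpolation by explicit bracket search."""
    if x <= xs[0]:
        return float(ys[0])
    if x >= xs[-1]:
        return float(ys[-1])
    for i in range(len(xs) - 1):
        if xs[i] <= x <= xs[i + 1]:
            w = (x - xs[i]) / (xs[i + 1] - xs[i])
            return float(ys[i] * (1 - w) + ys[i + 1] * w)
    raise AssertionError("unreachable")


def tsp_scores_bruteforce(X: np.ndarray, y: np.ndarray, i: int, j: int):
    """Primary/secondary TSP scores for (column i, column j) by counting."""
    gt = []
    for s in range(X.shape[0]):
        gt.append(1.0 if X[s, i] > X[s, j] else 0.0)
    gt = np.array(gt)
    p1 = gt[y == 1].sum() / (y == 1).sum()
    p0 = gt[y == 0].sum() / (y == 0).sum()
    # per-sample ranks by explicit pairwise counting (midranks for ties)
    ranks = np.empty_like(X)
    for s in range(X.shape[0]):
        for a in range(X.shape[1]):
            less = np.sum(X[s] < X[s, a])
            equal = np.sum(X[s] == X[s, a])
            ranks[s, a] = less + (equal + 1) / 2.0
    d = ranks[:, i] - ranks[:, j]
    sec = abs(d[y == 1].mean() - d[y == 0].mean())
    return abs(p1 - p0), sec


def auc_concordance(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the concordant-pair fraction, ties counted one half."""
    c = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                c += 1.0
            elif p == n:
                c += 0.5
    return c / (len(pos) * len(neg))


def lasso_logistic_grid_search(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    lo: float = -4.0,
    hi: float = 4.0,
    step: float = 1e-3,
) -> np.ndarray:
    """Exhaustive 2-D lattice minimization of the penalized deviance
    (no intercept; exactly two features)."""
    assert X.shape[1] == 2
    grid = np.arange(lo, hi + step / 2, step)
    best = None
    best_obj = np.inf
    for chunk in range(0, len(grid), 256):
        b1 = grid[chunk : chunk + 256]
        eta = (
            X[:, 0][None, None, :] * b1[:, None, None]
            + X[:, 1][None, None, :] * grid[None, :, None]
        )
        loss = (np.logaddexp(0.0, eta) - y[None, None, :] * eta).mean(axis=2)
        obj = loss + lam * (np.abs(b1)[:, None] + np.abs(grid)[None, :])
        i, j = np.unravel_index(np.argmin(obj), obj.shape)
        if obj[i, j] < best_obj:
            best_obj = obj[i, j]
            best = np.array([b1[i], grid[j]])
    return best


def wilcoxon_exact_two_sided(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p-value by enumerating all assignments."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}  # tie-free
    w_obs = sum(ranks[v] for v in a)
    na = len(a)
    mean_w = na * (n + 1) / 2.0
    count = 0
    total = 0
    all_ranks = list(range(1, n + 1))
    for comb in combinations(all_ranks, na):
        w = sum(comb)
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
        total += 1
    return count / total
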