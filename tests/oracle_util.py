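"""Independent oracles used by the test suite.

Deliberately naive implementations — enumeration, closed forms, direct
definitions — kept separate from the package so they can never share code
with the paths they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_upper_tail_exact(k: int, M: int, K: int, n: int) -> float:
    """P(overlap >= k) by exact rational enumeration over draw counts."""
    if k <= 0:
        return 1.0
    total = comb(M, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, i) * comb(M - K, n - i), total)
    return float(acc)


def hypergeom_upper_tail_bruteforce(k: int, universe: list, marked: set, n: int) -> float:
    """P(overlap >= k) by literally enumerating every draw of size n."""
    hits = total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(set(draw) & marked) >= k:
            hits += 1
    return hits / total


def least_squares_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination of the normal-equation linear fit."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 1.0  # constant y: the horizontal fit is exact
    return 1.0 - ss_res / ss_tot


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values from the step-up definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        adj[idx] = running
    return np.minimum(adj, 1.0)


def complete_linkage_merge_heights(columns: np.ndarray) -> list[float]:
    """Agglomerative complete-linkage merge heights over column vectors,
    computed by brute-force cluster tracking (Euclidean distance)."""
    n = columns.shape[1]
    clusters = [{i} for i in range(n)]
    d = {
        (i, j): float(np.linalg.norm(columns[:, i] - columns[:, j]))
        for i in range(n)
        for j in range(i + 1, n)
    }

    def cdist(a: set, b: set) -> float:
        return max(d[tuple(sorted((i, j)))] for i in a for j in b)

    heights = []
    while len(clusters) > 1:
        best = min(
            (
                (cdist(clusters[a], clusters[b]), a, b)
                for a in range(len(clusters))
                for b in range(a + 1, len(clusters))
            ),
            key=lambda t: t[0],
        )
        h, a, b = best
        heights.append(h)
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights
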