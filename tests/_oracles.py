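"""Independent reference implementations used only to check the package.

These deliberately use the most literal, brute-force formulation of each
definition so they share no code with the implementations they verify.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def levenshtein_dp(a: str, b: str) -> int:
    """Full quadratic DP edit distance."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = min(
                D[i - 1][j] + 1,
                D[i][j - 1] + 1,
                D[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return D[n][m]


def bh_stepup_literal(p: list[float]) -> list[float]:
    """q_(i) = min_{j>=i} p_(j)*m/j, straight from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_i, m + 1)), 1.0
        )
    return q


def fisher_two_sided(table) -> float:
    """Conditional hypergeometric two-sided p by exhaustive enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2

    def pmf(k: int) -> float:
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(N, c1)
        )

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    return sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= p_obs * (1 + 1e-9))


def wilcoxon_exact(x, y) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group labelings.

    Assumes no ties. Returns (U of first sample, p)."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(n + m), n):
        rsum = sum(i + 1 for i in combo)
        us.append(rsum - n * (n + 1) / 2)
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


def sliding_score_brute(scores: np.ndarray, seq_idx: np.ndarray) -> float:
    """Max positive-sum score of a base-index sequence over every offset."""
    w = scores.shape[0]
    n = len(seq_idx)
    best = 0.0
    for offset in range(-n + 1, w):
        total = 0.0
        for j, b in enumerate(seq_idx):
            col = offset + j
            if 0 <= col < w:
                s = scores[col, b]
                if s > 0:
                    total += s
        best = max(best, total)
    return best


def pairwise_nw_score(a: str, b: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Optimal global alignment score of two plain sequences."""
    n, m = len(a), len(b)
    D = np.empty((n + 1, m + 1))
    D[:, 0] = np.arange(n + 1) * gap
    D[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            D[i, j] = max(D[i - 1, j - 1] + s, D[i - 1, j] + gap, D[i, j - 1] + gap)
    return float(D[n, m])
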