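"""Numba kernels for dynamic time warping.

Two kernels: a full-matrix cost-only DP (the exact reference) and a
windowed DP with per-row column bounds plus backpointers, used both as the
FastDTW base case and for its refinement levels.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def dtw_full_cost(ax, ay, bx, by):  # pragma: no cover - exercised via wrappers
    """Exact DTW cost over the full n x m matrix (two-row storage)."""
    n = ax.shape[0]
    m = bx.shape[0]
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        dx = ax[0] - bx[j]
        dy = ay[0] - by[j]
        c = np.sqrt(dx * dx + dy * dy)
        prev[j] = c if j == 0 else c + prev[j - 1]
    for i in range(1, n):
        dx = ax[i] - bx[0]
        dy = ay[i] - by[0]
        cur[0] = np.sqrt(dx * dx + dy * dy) + prev[0]
        for j in range(1, m):
            dx = ax[i] - bx[j]
            dy = ay[i] - by[j]
            c = np.sqrt(dx * dx + dy * dy)
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = c + best
        prev, cur = cur, prev
    return prev[m - 1]


@njit(cache=True)
def dtw_window(ax, ay, bx, by, lo, hi):  # pragma: no cover - via wrappers
    """Windowed DTW: row i may visit columns lo[i]..hi[i] (inclusive).

    Requires lo[0] == 0 and hi[n-1] == m-1.  Returns (cost, path_i, path_j)
    with the optimal monotone alignment path in forward order.
    """
    n = ax.shape[0]
    m = bx.shape[0]
    maxw = 0
    for i in range(n):
        w = hi[i] - lo[i] + 1
        if w > maxw:
            maxw = w
    D = np.full((n, maxw), np.inf)
    bp = np.zeros((n, maxw), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(n):
        for jj in range(hi[i] - lo[i] + 1):
            j = lo[i] + jj
            dx = ax[i] - bx[j]
            dy = ay[i] - by[j]
            c = np.sqrt(dx * dx + dy * dy)
            if i == 0 and j == 0:
                D[0, jj] = c
                continue
            best = np.inf
            which = np.int8(0)
            if i > 0 and lo[i - 1] <= j - 1 <= hi[i - 1]:
                v = D[i - 1, j - 1 - lo[i - 1]]
                if v < best:
                    best = v
                    which = 0
            if i > 0 and lo[i - 1] <= j <= hi[i - 1]:
                v = D[i - 1, j - lo[i - 1]]
                if v < best:
                    best = v
                    which = 1
            if jj > 0:
                v = D[i, jj - 1]
                if v < best:
                    best = v
                    which = 2
            D[i, jj] = c + best
            bp[i, jj] = which
    cost = D[n - 1, m - 1 - lo[n - 1]]
    # backtrack
    max_len = n + m
    pi = np.empty(max_len, dtype=np.int64)
    pj = np.empty(max_len, dtype=np.int64)
    i = n - 1
    j = m - 1
    k = max_len
    while True:
        k -= 1
        pi[k] = i
        pj[k] = j
        if i == 0 and j == 0:
            break
        w = bp[i, j - lo[i]]
        if w == 0:
            i -= 1
            j -= 1
        elif w == 1:
            i -= 1
        else:
            j -= 1
    return cost, pi[k:], pj[k:]
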