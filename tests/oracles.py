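"""Independent reference implementations used only by the test suite.

These deliberately share no code with the package: the subsequence-DTW
oracle enumerates per-start alignment matrices instead of using
start-index memorization, and the HOG1D oracle is a direct per-sample
histogram loop.
"""

from __future__ import annotations

import numpy as np


def dtw_full(cost: np.ndarray) -> float:
    """Plain DTW alignment distance for a (len_q, len_t) cost matrix."""
    m, n = cost.shape
    D = np.full((m + 1, n + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            D[i, j] = cost[i - 1, j - 1] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[m, n])


def best_subsequence_naive(cost: np.ndarray) -> tuple[int, int, float]:
    """Exhaustive minimum over all (p, q) subsequence alignments.

    O(m^2) full DTW runs; only usable for very small m.  Returns
    (start, end_inclusive, distance).
    """
    m = cost.shape[0]
    best = (0, 0, np.inf)
    for p in range(m):
        for q in range(p, m):
            d = dtw_full(cost[p : q + 1])
            if d < best[2]:
                best = (p, q, d)
    return best


def best_subsequence(cost: np.ndarray) -> tuple[int, int, float]:
    """Minimum over all (p, q) subsequence alignments: one independent
    DTW matrix per start p, advanced jointly over stream time
    (vectorized over starts, sequential over template rows).

    Returns (start, end_inclusive, distance).  Cross-checked against
    :func:`best_subsequence_naive` on tiny inputs in the test suite.
    """
    m, n = cost.shape
    init = np.full(n + 1, np.inf)
    init[0] = 0.0  # a start consumes nothing yet: empty prefix
    V = np.empty((0, n + 1))  # V[p] = DP column of start p through time t
    best = (0, 0, np.inf)
    for t in range(m):
        prev = np.vstack([V, init])  # starts 0..t; p = t enters fresh
        cur = np.full_like(prev, np.inf)  # j = 0 unreachable once i > 0
        for j in range(1, n + 1):
            step_min = np.minimum(np.minimum(prev[:, j], prev[:, j - 1]), cur[:, j - 1])
            cur[:, j] = cost[t, j - 1] + step_min
        V = cur
        p = int(np.argmin(cur[:, n]))
        if cur[p, n] < best[2]:
            best = (p, t, float(cur[p, n]))
    return best


def hog1d_reference(
    window: np.ndarray, bins: int, intervals: int, scale: float
) -> np.ndarray:
    """Per-sample histogram-of-oriented-gradients of one subsequence.

    Central-difference gradients (one-sided at the edges), orientation
    arctan(scale * g) binned uniformly over (-pi/2, pi/2), votes weighted
    by sqrt(1 + (scale*g)^2), one histogram per near-equal interval.
    """
    w = np.asarray(window, dtype=float)
    l = w.size
    g = np.empty(l)
    for i in range(l):
        if i == 0:
            g[i] = w[1] - w[0]
        elif i == l - 1:
            g[i] = w[-1] - w[-2]
        else:
            g[i] = (w[i + 1] - w[i - 1]) / 2.0
    g = g * scale
    bounds = np.round(np.linspace(0, l, intervals + 1)).astype(int)
    out = np.zeros(intervals * bins)
    for k in range(intervals):
        for i in range(bounds[k], bounds[k + 1]):
            theta = np.arctan(g[i])
            b = int((theta + np.pi / 2) / np.pi * bins)
            b = min(max(b, 0), bins - 1)
            out[k * bins + b] += np.sqrt(1.0 + g[i] * g[i])
    return out
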