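"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is written as directly as possible (explicit loops, textbook
formulas) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_correlation(X: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation via the direct covariance formula."""
    n, p = X.shape
    out = np.empty((p, p))
    for i in range(p):
        for j in range(p):
            xi, xj = X[:, i], X[:, j]
            mi, mj = xi.mean(), xj.mean()
            cov = ((xi - mi) * (xj - mj)).sum()
            denom = math.sqrt(((xi - mi) ** 2).sum() * ((xj - mj) ** 2).sum())
            out[i, j] = cov / denom
    return out


def run_length_segments(mask, rate, min_segment, gap_tolerance):
    """Reference segment extraction by explicit run-length scanning.

    Interior bad runs strictly shorter than gap_tolerance (seconds) are
    bridged; good runs of at least min_segment survive.
    """
    mask = [bool(v) for v in mask]
    n = len(mask)
    # identify runs as (value, start, stop)
    runs = []
    start = 0
    for i in range(1, n + 1):
        if i == n or mask[i] != mask[start]:
            runs.append((mask[start], start, i))
            start = i
    # bridge interior short bad runs
    bridged = list(mask)
    for k, (val, a, b) in enumerate(runs):
        if not val and 0 < k < len(runs) - 1 and (b - a) / rate < gap_tolerance:
            for i in range(a, b):
                bridged[i] = True
    # collect surviving good runs
    segments = []
    i = 0
    while i < n:
        if bridged[i]:
            j = i
            while j < n and bridged[j]:
                j += 1
            if (j - i) / rate >= min_segment:
                segments.append((i, j))
            i = j
        else:
            i += 1
    return segments


def bh_stepup(pvalues, q):
    """Benjamini-Hochberg by direct step-up enumeration: reject the largest
    k with p_(k) <= k*q/m, and adjusted values by the usual running
    minimum."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = [False] * m
    for rank, idx in enumerate(order, start=1):
        if rank <= k_star:
            reject[idx] = True
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj, reject
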