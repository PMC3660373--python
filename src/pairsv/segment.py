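"""Piecewise-constant segmentation by backward elimination.

The depth signal is modelled as a sparse piecewise-constant vector.  The
fit proceeds by backward elimination over breakpoints: starting with a
breakpoint between every adjacent sample, the weakest breakpoint is removed
repeatedly -- merging its two flanking segments -- until every surviving
breakpoint scores at least ``t_threshold``.  The score of a breakpoint
between segments L and R is the two-sample statistic

    t = |mean(L) - mean(R)| / (sigma * sqrt(1/n_L + 1/n_R))

against a single robust noise scale sigma estimated from first differences
(MAD / sqrt(2)); removing the weakest breakpoint first makes the result
independent of position order.  This is the backward-elimination stage of
the sparse piecewise-constant segmentation family used for array CNV
calling, with ``t_threshold`` as the one sensitivity knob.

A heap with lazy invalidation keeps each merge O(log n); the whole fit is
O(n log n).
"""

from __future__ import annotations

import heapq
from typing import Optional

import numpy as np

DEFAULT_T = 5.0


def robust_sigma(y: np.ndarray) -> float:
    """Noise scale from the MAD of first differences (step-insensitive)."""
    if len(y) < 2:
        return 0.0
    d = np.diff(y)
    return float(1.4826 * np.median(np.abs(d)) / np.sqrt(2.0))


def segment_signal(
    y: np.ndarray,
    t_threshold: float = DEFAULT_T,
    sigma: Optional[float] = None,
) -> list[tuple[int, int, float]]:
    """Fit a piecewise-constant model to ``y``.

    Returns ``[(start, end, mean), ...]`` with half-open index ranges tiling
    ``[0, len(y))``.  A constant (or empty/singleton) signal yields a single
    segment.  With an exactly noise-free signal (sigma = 0) every level
    change is kept as a breakpoint.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n == 0:
        return []
    if n == 1:
        return [(0, 1, float(y[0]))]
    if sigma is None:
        sigma = robust_sigma(y)
    if sigma <= 0:
        # exact signal: breakpoints at value changes
        bps = np.flatnonzero(np.diff(y) != 0) + 1
        bounds = [0, *bps.tolist(), n]
        return [
            (bounds[i], bounds[i + 1], float(y[bounds[i]:bounds[i + 1]].mean()))
            for i in range(len(bounds) - 1)
        ]

    # doubly linked list of segments over arrays; node i = segment starting
    # at index i (while alive)
    prev = np.arange(n) - 1
    nxt = np.arange(n) + 1
    seg_sum = y.copy()
    seg_n = np.ones(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    version = np.zeros(n, dtype=np.int64)

    def score(i: int) -> float:
        j = nxt[i]
        mL = seg_sum[i] / seg_n[i]
        mR = seg_sum[j] / seg_n[j]
        return abs(mL - mR) / (sigma * np.sqrt(1.0 / seg_n[i] + 1.0 / seg_n[j]))

    heap: list[tuple[float, int, int]] = []
    for i in range(n - 1):
        heap.append((score(i), i, 0))
    heapq.heapify(heap)

    while heap:
        t, i, ver = heapq.heappop(heap)
        if not alive[i] or ver != version[i] or nxt[i] >= n:
            continue
        if t >= t_threshold:
            break
        # merge segment i with its right neighbour j
        j = nxt[i]
        seg_sum[i] += seg_sum[j]
        seg_n[i] += seg_n[j]
        alive[j] = False
        nxt[i] = nxt[j]
        if nxt[i] < n:
            prev[nxt[i]] = i
        version[i] += 1
        if nxt[i] < n:
            heapq.heappush(heap, (score(i), i, int(version[i])))
        p = prev[i]
        if p >= 0:
            version[p] += 1
            heapq.heappush(heap, (score(p), int(p), int(version[p])))

    out = []
    i = 0
    while i < n:
        j = nxt[i]
        out.append((int(i), int(j), float(seg_sum[i] / seg_n[i])))
        i = j
    return out


def changepoints(segments: list[tuple[int, int, float]]) -> list[int]:
    """Interior breakpoint indices of a segment list."""
    return [s for s, _, _ in segments[1:]]
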