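"""Numba kernels for the DTW dynamic programs.

Pointwise cost is the absolute difference (the Euclidean distance of two
scalars).  Two boundary conventions are used:

* fixed-start DTW (``_dtw_matrix``, ``_last_row_series``, ``_advance_column``):
  the first row/column accumulate, i.e. the alignment is anchored at (0, 0);
* SPRING subsequence recurrence (``_spring_*``): the first template row does
  not accumulate along the stream, so a match may start at any stream sample;
  per-cell start pointers track where the best alignment began.
"""
from __future__ import annotations

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=False)
def _dtw_matrix(x, y, window):
    """Full accumulated-cost matrix, optionally Sakoe–Chiba banded.

    ``window < 0`` disables the band.  Cells outside the band are +inf.
    """
    n, m = x.size, y.size
    D = np.full((n, m), INF)
    D[0, 0] = abs(x[0] - y[0])
    for j in range(1, m):
        if window >= 0 and abs(j) > window:
            break
        D[0, j] = D[0, j - 1] + abs(x[0] - y[j])
    for i in range(1, n):
        lo, hi = 0, m
        if window >= 0:
            # keep the band centred on the diagonal scaled to the two lengths
            c = int(round(i * (m - 1) / max(n - 1, 1)))
            lo, hi = max(0, c - window), min(m, c + window + 1)
        for j in range(lo, hi):
            c = abs(x[i] - y[j])
            if j == 0:
                D[i, 0] = D[i - 1, 0] + c
            else:
                best = D[i - 1, j - 1]
                if D[i - 1, j] < best:
                    best = D[i - 1, j]
                if D[i, j - 1] < best:
                    best = D[i, j - 1]
                D[i, j] = c + best
    return D


@njit(cache=False)
def _last_row_series(x, y):
    """d_t = D(t, m-1) for every stream prefix, fixed-start boundary.

    Rolling two columns of the transposed DP keeps memory at O(m).
    """
    n, m = x.size, y.size
    prev = np.empty(m)
    cur = np.empty(m)
    out = np.empty(n)
    # first stream sample: cumulative along the template
    cur[0] = abs(x[0] - y[0])
    for j in range(1, m):
        cur[j] = cur[j - 1] + abs(x[0] - y[j])
    out[0] = cur[m - 1]
    for i in range(1, n):
        for j in range(m):
            prev[j] = cur[j]
        cur[0] = prev[0] + abs(x[i] - y[0])
        for j in range(1, m):
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = abs(x[i] - y[j]) + best
        out[i] = cur[m - 1]
    return out


@njit(cache=False)
def _advance_column(prev, x_t, y, first):
    """Advance one stream sample of the fixed-start DP; returns the new column."""
    m = y.size
    cur = np.empty(m)
    if first:
        cur[0] = abs(x_t - y[0])
        for j in range(1, m):
            cur[j] = cur[j - 1] + abs(x_t - y[j])
        return cur
    cur[0] = prev[0] + abs(x_t - y[0])
    for j in range(1, m):
        best = prev[j - 1]
        if prev[j] < best:
            best = prev[j]
        if cur[j - 1] < best:
            best = cur[j - 1]
        cur[j] = abs(x_t - y[j]) + best
    return cur


@njit(cache=False)
def _spring_dend(x, y):
    """Template-end distance series under the SPRING subsequence recurrence."""
    n, m = x.size, y.size
    prev = np.empty(m)
    cur = np.empty(m)
    out = np.empty(n)
    for t in range(n):
        for j in range(m):
            prev[j] = cur[j]
        cur[0] = abs(x[t] - y[0])
        for j in range(1, m):
            best = cur[j - 1]
            if t > 0:
                if prev[j] < best:
                    best = prev[j]
                if prev[j - 1] < best:
                    best = prev[j - 1]
            cur[j] = abs(x[t] - y[j]) + best
        out[t] = cur[m - 1]
    return out


@njit(cache=False)
def _spring_search(x, y, tau):
    """SPRING subsequence matching: report disjoint matches with d <= tau.

    Returns (starts, ends, dists, count).  A match is emitted once every
    live alignment either exceeds the pending minimum or starts after the
    pending match's end — the standard disjointness condition — plus a final
    flush at the end of the stream.
    """
    n, m = x.size, y.size
    d_prev = np.empty(m)
    s_prev = np.empty(m, np.int64)
    d_cur = np.empty(m)
    s_cur = np.empty(m, np.int64)
    starts = np.empty(n, np.int64)
    ends = np.empty(n, np.int64)
    dists = np.empty(n)
    count = 0
    dmin = INF
    t_s = -1
    t_e = -1
    for t in range(n):
        for j in range(m):
            d_prev[j] = d_cur[j]
            s_prev[j] = s_cur[j]
        d_cur[0] = abs(x[t] - y[0])
        s_cur[0] = t
        for j in range(1, m):
            best = d_cur[j - 1]
            arg = s_cur[j - 1]
            if t > 0:
                if d_prev[j] < best:
                    best = d_prev[j]
                    arg = s_prev[j]
                if d_prev[j - 1] < best:
                    best = d_prev[j - 1]
                    arg = s_prev[j - 1]
            d_cur[j] = abs(x[t] - y[j]) + best
            s_cur[j] = arg
        if dmin <= tau:
            report = True
            for j in range(m):
                if d_cur[j] < dmin and s_cur[j] <= t_e:
                    report = False
                    break
            if report:
                starts[count] = t_s
                ends[count] = t_e
                dists[count] = dmin
                count += 1
                dmin = INF
                for j in range(m):
                    if s_cur[j] <= t_e:
                        d_cur[j] = INF
        if d_cur[m - 1] <= tau and d_cur[m - 1] < dmin:
            dmin = d_cur[m - 1]
            t_s = s_cur[m - 1]
            t_e = t
    if dmin <= tau:
        starts[count] = t_s
        ends[count] = t_e
        dists[count] = dmin
        count += 1
    return starts, ends, dists, count
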