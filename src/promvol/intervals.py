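"""Half-open genomic interval arithmetic on numpy arrays.

All intervals are BED-style 0-based half-open ``[start, end)``. Functions
operate on parallel ``starts``/``ends`` arrays; callers keep any per-interval
metadata alongside and index it with the returned masks.
"""

from __future__ import annotations

import numpy as np


def merge_intervals(starts, ends) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping or abutting intervals into a disjoint sorted set."""
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return starts.copy(), ends.copy()
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for i in range(1, len(s)):
        if s[i] <= out_e[-1]:  # abutting [a,b) [b,c) merges; overlap test below is strict
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def positions_in_intervals(pos, starts, ends) -> np.ndarray:
    """Boolean mask: is each position inside any (merged, sorted) interval?"""
    pos = np.asarray(pos, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def intervals_overlap_any(qstarts, qends, starts, ends) -> np.ndarray:
    """For each query interval, True iff it overlaps >=1 bp of the (merged,
    sorted) target set, under half-open arithmetic (abutment is not overlap)."""
    qstarts = np.asarray(qstarts, dtype=np.int64)
    qends = np.asarray(qends, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0 or qstarts.size == 0:
        return np.zeros(qstarts.shape, dtype=bool)
    # overlap iff some target with start < qend and end > qstart
    i = np.searchsorted(ends, qstarts, side="right")  # first target ending after qstart
    out = np.zeros(qstarts.shape, dtype=bool)
    ok = i < starts.size
    out[ok] = starts[i[ok]] < qends[ok]
    return out


def nearest_edge_distance(pos, starts, ends) -> np.ndarray:
    """Distance from each position to the nearest interval edge.

    0 when the position falls inside an interval. Edge distance is measured
    to ``start`` or to ``end - 1`` (the last contained base), so a position
    one base past an interval is at distance 1. Returns +inf for an empty set.
    """
    pos = np.asarray(pos, dtype=np.int64)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size == 0:
        return np.full(pos.shape, np.inf)
    inside = positions_in_intervals(pos, starts, ends)
    # distance to following interval's start
    j = np.searchsorted(starts, pos, side="left")
    d_next = np.where(j < starts.size, starts[np.minimum(j, starts.size - 1)] - pos, np.iinfo(np.int64).max)
    # distance to preceding interval's last base
    k = np.searchsorted(ends, pos, side="right") - 1
    have_prev = k >= 0
    d_prev = np.where(have_prev, pos - (ends[np.maximum(k, 0)] - 1), np.iinfo(np.int64).max)
    dist = np.minimum(d_next, d_prev).astype(float)
    dist[inside] = 0.0
    return dist
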