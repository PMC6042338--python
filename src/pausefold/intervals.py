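"""Small interval utilities (0-based, half-open) shared across modules."""

from __future__ import annotations

import numpy as np

__all__ = ["merge_intervals", "total_length", "complement_intervals",
           "subtract_intervals", "overlaps_any", "IntervalIndex"]


def merge_intervals(intervals):
    """Union of [start, end) intervals; returns a sorted, disjoint list."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def total_length(intervals) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def complement_intervals(intervals, size: int):
    """Complement within [0, size)."""
    out = []
    pos = 0
    for s, e in merge_intervals(intervals):
        s, e = max(s, 0), min(e, size)
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < size:
        out.append((pos, size))
    return out


def subtract_intervals(a, b):
    """Set difference a \\ b over merged interval lists."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    out = []
    j = 0
    for s, e in a:
        pos = s
        while j < len(b) and b[j][1] <= pos:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > pos:
                out.append((pos, bs))
            pos = max(pos, be)
            k += 1
        if pos < e:
            out.append((pos, e))
    return out


class IntervalIndex:
    """Overlap queries against a fixed interval set via binary search.

    Intervals are merged, so an overlap query answers "does [s, e) intersect
    the union by at least 1 bp".
    """

    def __init__(self, intervals):
        merged = merge_intervals(intervals)
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)

    def overlaps(self, start, end):
        """Vectorized: True where [start, end) intersects any interval."""
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros(np.broadcast(start, end).shape, dtype=bool)
        idx = np.searchsorted(self.starts, end, side="left")
        hit = idx > 0
        prev_end = np.where(hit, self.ends[np.maximum(idx - 1, 0)], 0)
        return hit & (prev_end > start)


def overlaps_any(start, end, intervals) -> bool:
    return bool(IntervalIndex(intervals).overlaps(start, end))
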