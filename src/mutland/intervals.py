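"""Interval arithmetic on sorted, half-open genomic intervals.

All functions operate on ``(n, 2)`` integer arrays of 0-based half-open
``[start, end)`` intervals on a single chromosome.  Inputs need not be
sorted or disjoint unless stated; outputs of :func:`merge` and the set
operations are always sorted and disjoint.  These primitives back the
accessibility-mask combination and the window bookkeeping, where an
off-by-one in a boundary silently shifts every downstream density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "merge",
    "intersect",
    "union",
    "complement",
    "total_length",
    "contains",
    "coverage_at_least",
    "clipped_length",
    "MaskSet",
]


def _as_array(intervals) -> np.ndarray:
    a = np.asarray(intervals, dtype=np.int64)
    if a.size == 0:
        return a.reshape(0, 2)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("intervals must be an (n, 2) array")
    if np.any(a[:, 0] >= a[:, 1]):
        bad = a[a[:, 0] >= a[:, 1]][0]
        raise ValueError(f"empty or inverted interval {tuple(bad)}")
    if np.any(a[:, 0] < 0):
        raise ValueError("negative interval start")
    return a


def merge(intervals) -> np.ndarray:
    """Sort and merge overlapping or bookended intervals."""
    a = _as_array(intervals)
    if len(a) == 0:
        return a
    a = a[np.lexsort((a[:, 1], a[:, 0]))]
    # an interval opens a new block iff it starts after the running max end
    run_end = np.maximum.accumulate(a[:, 1])
    new_block = np.empty(len(a), dtype=bool)
    new_block[0] = True
    new_block[1:] = a[1:, 0] > run_end[:-1]
    starts = a[new_block, 0]
    ends = np.maximum.reduceat(a[:, 1], np.flatnonzero(new_block))
    return np.stack([starts, ends], axis=1)


def total_length(intervals) -> int:
    a = merge(intervals)
    if len(a) == 0:
        return 0
    return int(np.sum(a[:, 1] - a[:, 0]))


def intersect(a, b) -> np.ndarray:
    """Set intersection of two interval sets."""
    a = merge(a)
    b = merge(b)
    if len(a) == 0 or len(b) == 0:
        return np.empty((0, 2), dtype=np.int64)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i, 0], b[j, 0])
        hi = min(a[i, 1], b[j, 1])
        if lo < hi:
            out.append((lo, hi))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def union(a, b) -> np.ndarray:
    a = _as_array(a)
    b = _as_array(b)
    if len(a) == 0:
        return merge(b)
    if len(b) == 0:
        return merge(a)
    return merge(np.concatenate([a, b]))


def complement(intervals, length: int) -> np.ndarray:
    """Complement within ``[0, length)``."""
    a = merge(intervals)
    if len(a) and a[-1, 1] > length:
        raise ValueError("interval extends past chromosome end")
    bounds = np.concatenate([[0], a.ravel(), [length]])
    gaps = bounds.reshape(-1, 2)
    return gaps[gaps[:, 0] < gaps[:, 1]]


def contains(intervals, positions) -> np.ndarray:
    """Boolean membership of each position in the (merged) interval set."""
    a = merge(intervals)
    pos = np.asarray(positions, dtype=np.int64)
    if len(a) == 0:
        return np.zeros(pos.shape, dtype=bool)
    idx = np.searchsorted(a[:, 0], pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.shape, dtype=bool)
    out[ok] = pos[ok] < a[idx[ok], 1]
    return out


def coverage_at_least(interval_sets: Sequence, k: int) -> np.ndarray:
    """Region covered by at least ``k`` of the given interval sets.

    Event-sweep over all endpoints; each set contributes coverage 0/1
    (internally merged first, so overlapping intervals within one set do
    not double count).
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    events = []
    for s in interval_sets:
        m = merge(s)
        if len(m):
            events.append(np.stack([m[:, 0], np.ones(len(m), dtype=np.int64)], axis=1))
            events.append(np.stack([m[:, 1], -np.ones(len(m), dtype=np.int64)], axis=1))
    if not events:
        return np.empty((0, 2), dtype=np.int64)
    ev = np.concatenate(events)
    order = np.lexsort((-ev[:, 1], ev[:, 0]))
    ev = ev[order]
    pos = ev[:, 0]
    cov = np.cumsum(ev[:, 1])
    # segment between consecutive event positions has the running coverage
    seg_start = pos[:-1]
    seg_end = pos[1:]
    seg_cov = cov[:-1]
    keep = (seg_cov >= k) & (seg_start < seg_end)
    return merge(np.stack([seg_start[keep], seg_end[keep]], axis=1))


def _coverage_prefix(a: np.ndarray):
    """Cumulative covered length strictly before each interval start."""
    lens = a[:, 1] - a[:, 0]
    pref = np.concatenate([[0], np.cumsum(lens)])
    return pref


def clipped_length(intervals, starts, ends) -> np.ndarray:
    """Covered bases of the interval set inside each ``[start, end)`` query.

    Vectorised over the query windows; used for per-window passing
    fractions where a per-window loop would dominate the runtime.
    """
    a = merge(intervals)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if len(a) == 0:
        return np.zeros(starts.shape, dtype=np.int64)
    pref = _coverage_prefix(a)

    def covered_before(x):
        # total covered length in [0, x)
        i = np.searchsorted(a[:, 0], x, side="right") - 1
        base = np.where(i >= 0, pref[np.clip(i, 0, None)], 0)
        part = np.where(
            i >= 0,
            np.clip(x - a[np.clip(i, 0, None), 0], 0, a[np.clip(i, 0, None), 1] - a[np.clip(i, 0, None), 0]),
            0,
        )
        return base + part

    return covered_before(ends) - covered_before(starts)


@dataclass
class MaskSet:
    """Per-chromosome pass intervals with provenance labels.

    ``intervals`` maps chromosome name to a sorted, disjoint ``(n, 2)``
    array of half-open pass intervals.  Provenance records which filters
    (mappability, callability, CNV, cross-reference consistency, ...)
    were combined to produce it.
    """

    intervals: dict
    provenance: tuple = ()

    def __post_init__(self):
        self.intervals = {c: merge(v) for c, v in self.intervals.items()}

    def chromosomes(self):
        return list(self.intervals)

    def pass_length(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return total_length(self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64)))
        return sum(total_length(v) for v in self.intervals.values())

    def contains(self, chrom: str, positions) -> np.ndarray:
        iv = self.intervals.get(chrom)
        if iv is None:
            return np.zeros(np.asarray(positions).shape, dtype=bool)
        return contains(iv, positions)

    def intersection(self, other: "MaskSet") -> "MaskSet":
        chroms = set(self.intervals) & set(other.intervals)
        return MaskSet(
            {c: intersect(self.intervals[c], other.intervals[c]) for c in chroms},
            provenance=tuple(self.provenance) + tuple(other.provenance),
        )

    def restricted(self, chrom: str) -> np.ndarray:
        return self.intervals.get(chrom, np.empty((0, 2), dtype=np.int64))
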