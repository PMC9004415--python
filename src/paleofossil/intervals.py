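"""Small half-open interval arithmetic used throughout the pipeline.

All intervals are 0-based half-open ``(start, end)`` tuples with
``end > start``.  These helpers are deliberately tiny and are checked
against per-base bitmap oracles in the test suite.
"""

from __future__ import annotations

from bisect import bisect_left
from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of intervals as a sorted list of disjoint intervals.

    Touching intervals (end == start) are merged.
    """
    ivs = sorted(intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in merge(intervals))


def covered_length(iv: Interval, others: Iterable[Interval]) -> int:
    """Number of bases of ``iv`` covered by the union of ``others``."""
    s0, e0 = iv
    n = 0
    for s, e in merge(others):
        lo, hi = max(s, s0), min(e, e0)
        if hi > lo:
            n += hi - lo
    return n


def coverage_fraction(iv: Interval, others: Iterable[Interval]) -> float:
    s0, e0 = iv
    if e0 <= s0:
        raise ValueError("empty interval")
    return covered_length(iv, others) / (e0 - s0)


def gap(a: Interval, b: Interval) -> int:
    """End-to-start gap between two intervals; 0 if they touch or overlap."""
    return max(0, max(a[0], b[0]) - min(a[1], b[1]))


class IntervalSet:
    """Mutable set of disjoint intervals supporting overlap queries.

    Used by the greedy overlap-resolution steps (keep a candidate only if
    it is disjoint from everything kept so far).  O(log n) per query.
    """

    def __init__(self) -> None:
        self._starts: List[int] = []
        self._ivs: List[Interval] = []

    def overlaps(self, s: int, e: int) -> bool:
        i = bisect_left(self._starts, e)
        # candidate intervals: the one before position i may span s
        if i > 0 and self._ivs[i - 1][1] > s:
            return True
        return i < len(self._ivs) and self._ivs[i][0] < e

    def add(self, s: int, e: int) -> None:
        i = bisect_left(self._starts, s)
        self._starts.insert(i, s)
        self._ivs.insert(i, (s, e))

    def __iter__(self):
        return iter(self._ivs)
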