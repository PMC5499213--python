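"""Interval arithmetic on 0-based half-open intervals.

All functions operate on plain ``(start, end)`` tuples grouped per sequence
name, or on ``numpy`` arrays of starts/ends.  Intervals are merged/unioned
with overlap OR adjacency (``[0,5)`` and ``[5,9)`` merge to ``[0,9)``) so a
union is always a minimal sorted disjoint set.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Union-merge intervals into a sorted disjoint list."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    out: List[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def intersect_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total bp shared between two interval lists (each merged internally)."""
    am, bm = merge_intervals(a), merge_intervals(b)
    i = j = 0
    bp = 0
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if e > s:
            bp += e - s
        if am[i][1] < bm[j][1]:
            i += 1
        else:
            j += 1
    return bp


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Intervals covered by both lists."""
    am, bm = merge_intervals(a), merge_intervals(b)
    i = j = 0
    out: List[Interval] = []
    while i < len(am) and j < len(bm):
        s = max(am[i][0], bm[j][0])
        e = min(am[i][1], bm[j][1])
        if e > s:
            out.append((s, e))
        if am[i][1] < bm[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Bases of ``a`` not covered by ``b``."""
    am, bm = merge_intervals(a), merge_intervals(b)
    out: List[Interval] = []
    j = 0
    for s, e in am:
        cur = s
        while j < len(bm) and bm[j][1] <= cur:
            j += 1
        k = j
        while k < len(bm) and bm[k][0] < e:
            if bm[k][0] > cur:
                out.append((cur, bm[k][0]))
            cur = max(cur, bm[k][1])
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def reciprocal_overlap(a: Interval, b: Interval) -> float:
    """min(overlap/len(a), overlap/len(b)); 0 if either is empty."""
    la, lb = a[1] - a[0], b[1] - b[0]
    if la <= 0 or lb <= 0:
        return 0.0
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / la, ov / lb)


class CoverageIndex:
    """O(1) masked-bp lookup for arbitrary intervals via a prefix-sum.

    Built once from a merged interval set on a sequence of known length;
    ``covered_bp(starts, ends)`` is vectorised, which makes the permutation
    null of the TE-enrichment test cheap.
    """

    def __init__(self, intervals: Sequence[Interval], seq_length: int):
        self.seq_length = int(seq_length)
        merged = merge_intervals(intervals)
        cov = np.zeros(self.seq_length + 1, dtype=np.int64)
        for s, e in merged:
            if s < 0 or e > self.seq_length:
                raise ValueError(f"interval ({s},{e}) outside sequence of length {seq_length}")
            cov[s] += 1
            cov[e] -= 1
        self._prefix = np.concatenate([[0], np.cumsum(np.cumsum(cov)[:-1])])

    def covered_bp(self, starts, ends):
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        return self._prefix[ends] - self._prefix[starts]


def merge_by_seq(records: Iterable[Tuple[str, int, int]]) -> Dict[str, List[Interval]]:
    """Group (seq, start, end) triples by seq and union-merge each group."""
    by: Dict[str, List[Interval]] = {}
    for seq, s, e in records:
        by.setdefault(seq, []).append((s, e))
    return {seq: merge_intervals(ivs) for seq, ivs in by.items()}
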