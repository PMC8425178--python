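"""Interval arithmetic on circular genomes.

Intervals are 0-based half-open ``(start, end)`` pairs; ``end`` may exceed
the genome length ``L`` to denote an origin-spanning interval (end <= start+L).
"""

from __future__ import annotations

import numpy as np


def linear_parts(start: int, end: int, L: int) -> list[tuple[int, int]]:
    """Split a (possibly origin-spanning) interval into linear pieces."""
    if end < start:
        raise ValueError("end < start")
    if end - start > L:
        raise ValueError("interval longer than genome")
    start %= L
    end = start + (end - start)
    if end <= L:
        return [(start, end)] if end > start else []
    return [(start, L), (0, end - L)]


def coverage_mask(intervals, L: int) -> np.ndarray:
    mask = np.zeros(L, dtype=bool)
    for s, e in intervals:
        for a, b in linear_parts(s, e, L):
            mask[a:b] = True
    return mask


def union_length(intervals, L: int) -> int:
    return int(coverage_mask(intervals, L).sum())


def complement_intervals(intervals, L: int, circular: bool = True):
    """Intervals not covered; on circles a wrap gap is one end>L interval."""
    mask = coverage_mask(intervals, L)
    free = ~mask
    if not free.any():
        return []
    if free.all():
        return [(0, L)]
    idx = np.flatnonzero(np.diff(np.concatenate(([0], free.view(np.int8), [0]))))
    runs = [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]
    if circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1] + [(last[0], L + first[1])]
    return runs


def overlap_length(a, b, L: int) -> int:
    """Overlap in bp between two circular intervals."""
    mask = coverage_mask([a], L) & coverage_mask([b], L)
    return int(mask.sum())


def reciprocal_overlap(a, b, L: int) -> float:
    ov = overlap_length(a, b, L)
    la, lb = a[1] - a[0], b[1] - b[0]
    if la == 0 or lb == 0:
        return 0.0
    return min(ov / la, ov / lb)


def interval_length(iv) -> int:
    return iv[1] - iv[0]
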