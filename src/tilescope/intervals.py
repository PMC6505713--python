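"""Arithmetic on 1-based inclusive genomic intervals.

Small, heavily reused primitives: overlap length, merging, coverage and
merged-set intersection.  Everything here treats an interval as a
``(start, end)`` pair with ``start <= end``, both inclusive.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Number of shared nucleotides between two inclusive intervals.

    Adjacency is not overlap: ``[100, 200]`` vs ``[201, 300]`` -> 0.
    """
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals as a sorted list of disjoint intervals.

    Touching intervals (gap 0, e.g. [1,10] and [11,20]) are merged, which is
    correct for nucleotide-coverage accounting.
    """
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"invalid interval [{s}, {e}]")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def coverage(merged: Sequence[tuple[int, int]]) -> int:
    """Total nucleotides covered by a disjoint (merged) interval list."""
    return sum(e - s + 1 for s, e in merged)


def intersect_merged(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two merged interval lists, as a merged list."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def union_coverage(intervals: Iterable[tuple[int, int]]) -> int:
    """Nucleotides covered by the union of arbitrary intervals."""
    return coverage(merge_intervals(intervals))
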