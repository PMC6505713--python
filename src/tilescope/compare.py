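"""Interval-set meta-comparison between detected regions and published
prediction sets: intersection/union candidate counts, per-candidate overlap
fractions, nucleotide-level coverage comparison, and presence
classification of predictions against the detected transcriptome.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import (
    coverage,
    intersect_merged,
    merge_intervals,
    overlap_length,
)
from .types import Region

log = logging.getLogger(__name__)

#: An interval with optional strand: (start, end) or (start, end, strand).
Interval = tuple


def _strand_of(iv: Interval) -> str | None:
    return iv[2] if len(iv) > 2 else None


@dataclass
class PredictionSet:
    """A named set of predicted transcript intervals (strand optional)."""

    name: str
    intervals: list[Interval]
    provenance: str = ""

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv[0] > iv[1]:
                raise ValueError(f"invalid interval {iv} in set {self.name!r}")
        self.stranded = all(_strand_of(iv) in ("+", "-") for iv in self.intervals)
        if not self.stranded and self.intervals:
            log.info(
                "prediction set %s lacks strand information: "
                "comparisons will be strand-agnostic",
                self.name,
            )


def _overlaps(a: Interval, b: Interval, min_overlap: int) -> bool:
    sa, sb = _strand_of(a), _strand_of(b)
    if sa is not None and sb is not None and sa != sb:
        return False
    return overlap_length((a[0], a[1]), (b[0], b[1])) >= min_overlap


def set_intersection_union(
    set_a: PredictionSet, set_b: PredictionSet, min_overlap: int = 1
) -> tuple[int, int, dict[int, list[int]]]:
    """Candidate-level intersection and union of two prediction sets.

    An A-candidate is "present in both" when it overlaps at least
    ``min_overlap`` nt with one or more B-candidates (strand-aware only when
    both sets carry strand).  One-to-many overlaps are collapsed by
    candidate: intersection = number of matched A-candidates, and
    union = |A| + |B| - intersection.  The overlap map gives, per
    A-candidate index, the indices of its B partners.
    """
    if not set_a.intervals or not set_b.intervals:
        raise ValueError("both prediction sets must be non-empty")
    tree = IntervalTree()
    for j, b in enumerate(set_b.intervals):
        tree[b[0] : b[1] + 1] = j
    overlap_map: dict[int, list[int]] = {}
    for i, a in enumerate(set_a.intervals):
        partners = []
        for hit in tree[a[0] : a[1] + 1]:
            b = set_b.intervals[hit.data]
            if _overlaps(a, b, min_overlap):
                partners.append(hit.data)
        if partners:
            overlap_map[i] = sorted(partners)
    intersection = len(overlap_map)
    union = len(set_a.intervals) + len(set_b.intervals) - intersection
    return intersection, union, overlap_map


def overlap_fraction(region: Interval, prediction: Interval) -> int:
    """Percent of the region covered by the prediction, as an integer.

    Rounds half away from zero, matching integer-percent report tables.
    """
    region_len = region[1] - region[0] + 1
    ov = overlap_length((region[0], region[1]), (prediction[0], prediction[1]))
    return int(math.floor(100.0 * ov / region_len + 0.5))


def nucleotide_coverage_compare(
    set_a: Sequence[Interval],
    set_b: Sequence[Interval],
    genome_length: int,
) -> tuple[int, int, int]:
    """Nucleotides covered only by A, only by B, and by both.

    Computed on the per-nucleotide union of each set, strand-collapsed; the
    three counts sum to the coverage of A union B.
    """
    for iv in list(set_a) + list(set_b):
        if iv[1] > genome_length or iv[0] < 1:
            raise ValueError(f"interval {iv} exceeds genome bounds")
    merged_a = merge_intervals([(iv[0], iv[1]) for iv in set_a]) if set_a else []
    merged_b = merge_intervals([(iv[0], iv[1]) for iv in set_b]) if set_b else []
    cov_a = coverage(merged_a)
    cov_b = coverage(merged_b)
    shared = coverage(intersect_merged(merged_a, merged_b))
    return cov_a - shared, cov_b - shared, shared


def classify_predictions(
    predictions: PredictionSet,
    differential: Sequence[Region],
    similar: Sequence[Region],
    min_overlap: int = 1,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Assign each prediction to every presence column it overlaps.

    Columns: present in reference / present in treated (from the presence
    flags of any overlapped region), similarly expressed, differentially
    expressed, and present in neither condition.  A prediction may count in
    both "similarly" and "differentially"; the columns are not exclusive.
    """
    tree = IntervalTree()
    for r in differential:
        tree[r.start : r.end + 1] = ("differential", r)
    for r in similar:
        tree[r.start : r.end + 1] = ("similar", r)

    rows = []
    for i, p in enumerate(predictions.intervals):
        in_ref = in_trt = in_sim = in_diff = False
        for hit in tree[p[0] : p[1] + 1]:
            kind, r = hit.data
            strand = _strand_of(p)
            if strand is not None and strand != r.strand:
                continue
            if overlap_length((p[0], p[1]), (r.start, r.end)) < min_overlap:
                continue
            in_ref = in_ref or r.present_reference
            in_trt = in_trt or r.present_treated
            in_diff = in_diff or kind == "differential"
            in_sim = in_sim or kind == "similar"
        rows.append(
            {
                "prediction": i,
                "start": p[0],
                "end": p[1],
                "present_reference": in_ref,
                "present_treated": in_trt,
                "similarly_expressed": in_sim,
                "differentially_expressed": in_diff,
                "present_neither": not (in_ref or in_trt),
            }
        )
    df = pd.DataFrame(rows)
    counts = {
        "predicted_total": len(predictions.intervals),
        "present_reference": int(df["present_reference"].sum()) if len(df) else 0,
        "present_treated": int(df["present_treated"].sum()) if len(df) else 0,
        "similarly_expressed": int(df["similarly_expressed"].sum()) if len(df) else 0,
        "differentially_expressed": (
            int(df["differentially_expressed"].sum()) if len(df) else 0
        ),
        "present_neither": int(df["present_neither"].sum()) if len(df) else 0,
    }
    return counts, df
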