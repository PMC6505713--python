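"""Annotation-independent segmentation of probe-intensity series.

Probes on one strand, sorted by start, are first split into runs wherever
consecutive probe starts are more than ``max_gap`` nt apart (untiled
sequence must not be bridged).  Within each run an exact change-point
partition is found by dynamic programming minimising

    total cost = sum over segments [ RSS_ref + RSS_treated ] + lambda * k

where RSS_c is the residual sum of squares of all probe x replicate values
in condition c around the segment's condition mean and k is the number of
segments.  Each segment is then scored for differential expression exactly
like an annotated gene (pooled Welch t), its genomic extent being the first
probe start to the last probe end.  Regions are called differential
(P > 0.95, |log2FC| > 0.5, length >= 25 nt) or similarly expressed (present
in at least one condition, length > 35 nt).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .intervals import union_coverage
from .stats import welch_de
from .types import IntensityMatrix, Probe, Region

log = logging.getLogger(__name__)

DEFAULT_PENALTY = 6.0
DEFAULT_MAX_GAP = 60


def _split_runs(starts: np.ndarray, max_gap: int) -> list[slice]:
    """Slices of consecutive probes whose start spacing is <= max_gap."""
    if len(starts) == 0:
        return []
    breaks = np.flatnonzero(np.diff(starts) > max_gap)
    edges = [0, *(breaks + 1), len(starts)]
    return [slice(a, b) for a, b in zip(edges[:-1], edges[1:])]


def _dp_partition(costs_prefix, penalty: float, n: int) -> list[tuple[int, int]]:
    """Optimal partition of probes 0..n-1 by least-squares DP.

    ``costs_prefix`` is a list of per-condition prefix arrays (S1, S2, N)
    of length n+1 so a segment cost is O(1); the DP is O(n^2) with the
    inner minimisation vectorised.
    Returns inclusive (first, last) probe-index pairs.
    """
    best = np.empty(n + 1)
    best[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        rss = np.zeros(j)
        for s1, s2, cnt in costs_prefix:
            ds1 = s1[j] - s1[:j]
            ds2 = s2[j] - s2[:j]
            dn = cnt[j] - cnt[:j]
            rss += ds2 - ds1 * ds1 / dn
        total = best[:j] + rss + penalty
        k = int(np.argmin(total))
        best[j] = total[k]
        back[j] = k
    segments: list[tuple[int, int]] = []
    j = n
    while j > 0:
        i = back[j]
        segments.append((i, j - 1))
        j = i
    segments.reverse()
    return segments


def segment_series(
    probe_rows: Sequence[int],
    starts: Sequence[int],
    matrix: IntensityMatrix,
    penalty: float = DEFAULT_PENALTY,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[list[int]]:
    """Segment one strand's probe series into change-point segments.

    ``probe_rows`` are matrix row indices sorted by genomic ``starts``.
    Returns a list of segments, each a list of matrix row indices.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    probe_rows = np.asarray(probe_rows, dtype=int)
    starts = np.asarray(starts, dtype=int)
    if np.any(np.diff(starts) < 0):
        raise ValueError("probes must be sorted by start")
    segments: list[list[int]] = []
    for run in _split_runs(starts, max_gap):
        rows = probe_rows[run]
        n = len(rows)
        if n == 1:
            segments.append([int(rows[0])])
            continue
        prefixes = []
        for condition in ("reference", "treated"):
            vals = matrix.values[np.ix_(rows, matrix.columns(condition))]
            row_sum = vals.sum(axis=1)
            row_sq = (vals * vals).sum(axis=1)
            row_n = np.full(n, vals.shape[1], dtype=float)
            prefixes.append(
                (
                    np.concatenate([[0.0], np.cumsum(row_sum)]),
                    np.concatenate([[0.0], np.cumsum(row_sq)]),
                    np.concatenate([[0.0], np.cumsum(row_n)]),
                )
            )
        for first, last in _dp_partition(prefixes, penalty, n):
            segments.append([int(r) for r in rows[first : last + 1]])
    return segments


def segment_cost(
    rows: Sequence[int], matrix: IntensityMatrix
) -> float:
    """RSS_ref + RSS_treated of one segment (used by callers and oracles)."""
    cost = 0.0
    rows = np.asarray(rows, dtype=int)
    for condition in ("reference", "treated"):
        vals = matrix.values[np.ix_(rows, matrix.columns(condition))].ravel()
        cost += float(np.sum((vals - vals.mean()) ** 2))
    return cost


def score_region(
    segment_rows: Sequence[int],
    layout: Sequence[Probe],
    matrix: IntensityMatrix,
    region_id: str,
    floor: float = 9.0,
) -> Region:
    """Score one segment: pooled Welch P, log2FC and presence flags."""
    rows = np.asarray(segment_rows, dtype=int)
    probes = [layout[r] for r in rows]
    ref = matrix.pooled(rows, "reference")
    trt = matrix.pooled(rows, "treated")
    p_score, fc = welch_de(ref, trt)
    mean_ref, mean_trt = float(ref.mean()), float(trt.mean())
    return Region(
        id=region_id,
        strand=probes[0].strand,
        start=min(p.start for p in probes),
        end=max(p.end for p in probes),
        mean_reference=mean_ref,
        mean_treated=mean_trt,
        p_score=p_score,
        log2_fold_change=fc,
        present_reference=mean_ref >= floor,
        present_treated=mean_trt >= floor,
        n_probes=len(probes),
    )


def segment_genome(
    layout: Sequence[Probe],
    matrix: IntensityMatrix,
    penalty: float = DEFAULT_PENALTY,
    max_gap: int = DEFAULT_MAX_GAP,
    floor: float = 9.0,
) -> list[Region]:
    """Segment both strands of the whole layout and score every segment.

    Probes are assumed to be in the same order in ``layout`` and in the
    matrix rows.
    """
    regions: list[Region] = []
    counter = 0
    for strand in ("+", "-"):
        idx = [i for i, p in enumerate(layout) if p.strand == strand]
        idx.sort(key=lambda i: (layout[i].start, layout[i].end))
        starts = [layout[i].start for i in idx]
        for seg in segment_series(idx, starts, matrix, penalty, max_gap):
            counter += 1
            regions.append(
                score_region(seg, layout, matrix, f"region_{counter:05d}", floor)
            )
    return regions


def call_regions(
    regions: Sequence[Region],
    p_threshold: float = 0.95,
    fc_threshold: float = 0.5,
    min_de_length: int = 25,
    min_expr_length: int = 35,
) -> tuple[list[Region], list[Region]]:
    """Partition scored regions into differential and similarly expressed.

    Differential: P > ``p_threshold``, |log2FC| > ``fc_threshold`` and
    length >= ``min_de_length``.  Similarly expressed: not differential,
    present in at least one condition, and length strictly greater than
    ``min_expr_length``.  A region meeting both sets of criteria appears
    only in the differential list; regions failing the length floors are
    dropped with a logged count.
    """
    differential: list[Region] = []
    similar: list[Region] = []
    dropped_short_de = dropped_short_expr = 0
    for r in regions:
        is_de_signal = (
            r.p_score > p_threshold and abs(r.log2_fold_change) > fc_threshold
        )
        expressed = r.present_reference or r.present_treated
        if is_de_signal and expressed:
            if r.length >= min_de_length:
                r.call = "differential"
                differential.append(r)
                continue
            dropped_short_de += 1
        if expressed:
            if r.length > min_expr_length:
                r.call = "similar_expressed"
                similar.append(r)
            else:
                dropped_short_expr += 1
        else:
            r.call = "not_expressed"
    if dropped_short_de or dropped_short_expr:
        log.info(
            "length floors dropped %d differential and %d expressed regions",
            dropped_short_de,
            dropped_short_expr,
        )
    return differential, similar


def count_expressed_nucleotides(
    regions: Sequence[Region], condition: str
) -> int:
    """Union length (nt) of regions present in one condition, per strand.

    Overlapping regions are counted once; strands are unioned separately and
    summed.
    """
    flag = {
        "reference": lambda r: r.present_reference,
        "treated": lambda r: r.present_treated,
    }[condition]
    total = 0
    for strand in ("+", "-"):
        ivs = [(r.start, r.end) for r in regions if r.strand == strand and flag(r)]
        if ivs:
            total += union_coverage(ivs)
    return total


def calibrate_penalty(
    penalties: Sequence[float],
    n_series: int = 200,
    n_probes: int = 60,
    noise_sd: float = 0.3,
    n_replicates: int = 5,
    seed: int = 0,
) -> dict[float, float]:
    """Fraction of pure-noise series yielding a single segment, per penalty.

    The default penalty is chosen as the smallest value for which at least
    99% of pure-noise series stay unsplit.
    """
    from .types import IntensityMatrix as IM

    rng = np.random.default_rng(seed)
    results = {float(lam): 0 for lam in penalties}
    for _ in range(n_series):
        values = rng.normal(7.5, noise_sd, size=(n_probes, 2 * n_replicates))
        matrix = IM(
            probe_ids=[f"p{i}" for i in range(n_probes)],
            values=values,
            conditions=["reference"] * n_replicates + ["treated"] * n_replicates,
            replicates=list(range(1, n_replicates + 1)) * 2,
        )
        starts = list(range(1, 14 * n_probes, 14))
        for lam in results:
            segs = segment_series(
                list(range(n_probes)), starts, matrix, penalty=lam
            )
            if len(segs) == 1:
                results[lam] += 1
    return {lam: hits / n_series for lam, hits in results.items()}
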