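"""Annotation-based differential expression.

For every annotated gene, all probes whose midpoint falls inside the gene on
the gene's strand are pooled (probe x replicate) per condition and compared
with a Welch two-sample t-test.  A gene is "present" in a condition when its
pooled mean is at or above the detection floor (default 9.0 log2); a gene
present in exactly one condition is called absent in the other and counted
with the down- (or up-) regulated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .stats import welch_de
from .types import GeneFeature, IntensityMatrix, Probe

log = logging.getLogger(__name__)

#: Differential-expression statuses, in reporting order.
DE_STATUSES = (
    "up",
    "down",
    "similar",
    "absent_both",
    "absent_treated_only",
    "absent_reference_only",
)


@dataclass
class DECall:
    """Per-gene differential-expression call."""

    feature_id: str
    n_probes: int
    mean_reference: float
    mean_treated: float
    log2_fold_change: float
    p_score: float
    status: str


def gene_probe_map(
    layout: Sequence[Probe], genes: Sequence[GeneFeature]
) -> tuple[dict[str, list[str]], list[str]]:
    """Map each gene to the probes targeting it (midpoint rule, strand-aware).

    Returns ``(mapping, untestable)`` where ``untestable`` lists genes with
    zero probes; these are reported, never silently dropped.
    """
    trees = {"+": IntervalTree(), "-": IntervalTree()}
    for g in genes:
        trees[g.strand][g.start : g.end + 1] = g.id
    mapping: dict[str, list[str]] = {g.id: [] for g in genes}
    for p in layout:
        for iv in trees[p.strand][p.midpoint]:
            mapping[iv.data].append(p.id)
    untestable = [gid for gid, probes in mapping.items() if not probes]
    if untestable:
        log.warning("%d genes have no targeting probe", len(untestable))
    return mapping, untestable


def test_gene(
    probe_ids: Sequence[str], matrix: IntensityMatrix
) -> tuple[float, float, float, float]:
    """Welch test over the pooled probe x replicate values of one gene.

    Returns ``(p_score, log2_fold_change, mean_reference, mean_treated)``.
    """
    rows = matrix.rows(probe_ids)
    ref = matrix.pooled(rows, "reference")
    trt = matrix.pooled(rows, "treated")
    p_score, fc = welch_de(ref, trt)
    return p_score, fc, float(ref.mean()), float(trt.mean())


def call_annotated(
    genes: Sequence[GeneFeature],
    layout: Sequence[Probe],
    matrix: IntensityMatrix,
    p_threshold: float = 0.95,
    fc_threshold: float = 0.5,
    floor: float = 9.0,
) -> tuple[list[DECall], dict[str, int], list[str]]:
    """Call every testable gene up/down/similar/absent.

    Rules: presence per condition is pooled mean >= ``floor``.  A gene
    present in both conditions is ``up`` (``down``) when P > ``p_threshold``
    and log2FC exceeds ``fc_threshold`` in magnitude with the matching sign,
    else ``similar``.  Presence in exactly one condition is
    ``absent_treated_only`` / ``absent_reference_only`` (counted with the
    down- and up-regulated genes in the summary); presence in neither is
    ``absent_both``.
    """
    if p_threshold <= 0 or fc_threshold <= 0:
        raise ValueError("thresholds must be positive")
    mapping, untestable = gene_probe_map(layout, genes)
    calls: list[DECall] = []
    for g in genes:
        probes = mapping[g.id]
        if not probes:
            continue
        p_score, fc, mean_ref, mean_trt = test_gene(probes, matrix)
        present_ref = mean_ref >= floor
        present_trt = mean_trt >= floor
        if present_ref and present_trt:
            if p_score > p_threshold and fc > fc_threshold:
                status = "up"
            elif p_score > p_threshold and fc < -fc_threshold:
                status = "down"
            else:
                status = "similar"
        elif present_ref:
            status = "absent_treated_only"
        elif present_trt:
            status = "absent_reference_only"
        else:
            status = "absent_both"
        calls.append(
            DECall(
                feature_id=g.id,
                n_probes=len(probes),
                mean_reference=mean_ref,
                mean_treated=mean_trt,
                log2_fold_change=fc,
                p_score=p_score,
                status=status,
            )
        )
    summary = {s: 0 for s in DE_STATUSES}
    for c in calls:
        summary[c.status] += 1
    summary["downregulated_total"] = (
        summary["down"] + summary["absent_treated_only"]
    )
    summary["upregulated_total"] = summary["up"] + summary["absent_reference_only"]
    summary["testable"] = len(calls)
    return calls, summary, untestable


def calls_to_frame(calls: Sequence[DECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.feature_id,
                c.n_probes,
                c.mean_reference,
                c.mean_treated,
                c.log2_fold_change,
                c.p_score,
                c.status,
            )
            for c in calls
        ],
        columns=[
            "gene_id",
            "n_probes",
            "mean_ref",
            "mean_treated",
            "log2FC",
            "P",
            "status",
        ],
    )
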