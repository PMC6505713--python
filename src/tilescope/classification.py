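"""Mapping detected regions to the annotation.

Categories, evaluated in fixed precedence:

touching
    same-strand overlap of at least one nucleotide with a gene;
operon_element
    a same-strand gene within <100 nt (gap, exclusive of both ends) on both
    sides — suggesting the region is internal to a co-transcribed unit;
utr5 / utr3
    one same-strand gene end within <100 nt; the side is strand-aware (a
    region upstream of a + gene's start, or genomically downstream of a
    - gene's end, is that gene's 5' UTR);
antisense
    overlap only with genes on the opposite strand (removed from most
    downstream analyses, since their validity cannot be established);
novel
    none of the above.

The precedence (touching > operon_element > utr5/utr3 > antisense > novel)
makes the most annotation-anchored label win; operon beats UTR because its
requirement (two flanking genes) is strictly stronger.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import overlap_length as _interval_overlap
from .types import GeneFeature, Region

log = logging.getLogger(__name__)

CATEGORIES = ("touching", "operon_element", "utr5", "utr3", "antisense", "novel")


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Shared nucleotides of two 1-based inclusive intervals (0 if disjoint)."""
    return _interval_overlap(a, b)


@dataclass
class Classification:
    """A region's category and the genes anchoring it."""

    region_id: str
    category: str
    gene_ids: tuple[str, ...] = ()
    distances: tuple[int, ...] = ()


class AnnotationIndex:
    """Strand-aware interval and neighbour index over gene features."""

    def __init__(self, genes: Sequence[GeneFeature]) -> None:
        self.trees = {"+": IntervalTree(), "-": IntervalTree()}
        self._by_strand: dict[str, list[GeneFeature]] = {"+": [], "-": []}
        for g in genes:
            self.trees[g.strand][g.start : g.end + 1] = g
            self._by_strand[g.strand].append(g)
        self._starts: dict[str, list[int]] = {}
        for strand, gs in self._by_strand.items():
            gs.sort(key=lambda g: (g.start, g.end))
            self._starts[strand] = [g.start for g in gs]
        self._end_sorted = {
            strand: sorted(gs, key=lambda g: (g.end, g.start))
            for strand, gs in self._by_strand.items()
        }
        self._end_keys = {
            strand: [g.end for g in gs] for strand, gs in self._end_sorted.items()
        }

    def overlapping(self, strand: str, start: int, end: int) -> list[GeneFeature]:
        hits = [iv.data for iv in self.trees[strand][start : end + 1]]
        return sorted(hits, key=lambda g: (g.start, g.end))

    def left_neighbour(self, strand: str, pos: int) -> GeneFeature | None:
        """Nearest same-strand gene ending strictly before ``pos``."""
        i = bisect_left(self._end_keys[strand], pos)
        return self._end_sorted[strand][i - 1] if i > 0 else None

    def right_neighbour(self, strand: str, pos: int) -> GeneFeature | None:
        """Nearest same-strand gene starting strictly after ``pos``."""
        i = bisect_right(self._starts[strand], pos)
        gs = self._by_strand[strand]
        return gs[i] if i < len(gs) else None


def _utr_side(gene: GeneFeature, gene_is_right: bool) -> str:
    """UTR side for a region flanking ``gene`` on the given genomic side."""
    if gene_is_right:  # region sits before the gene's genomic start
        return "utr5" if gene.strand == "+" else "utr3"
    return "utr3" if gene.strand == "+" else "utr5"


def classify_region(
    region: Region, index: AnnotationIndex, utr_cutoff: int = 100
) -> Classification:
    """Classify one region against the annotation (precedence as per module doc).

    Distances are gap nucleotide counts, exclusive of both the region end and
    the gene end; "< 100 nt" is a strict inequality on that gap.
    """
    same = index.overlapping(region.strand, region.start, region.end)
    if same:
        return Classification(
            region_id=region.id,
            category="touching",
            gene_ids=tuple(g.id for g in same),
            distances=tuple(0 for _ in same),
        )

    left = index.left_neighbour(region.strand, region.start)
    right = index.right_neighbour(region.strand, region.end)
    left_gap = region.start - left.end - 1 if left is not None else None
    right_gap = right.start - region.end - 1 if right is not None else None
    left_near = left_gap is not None and left_gap < utr_cutoff
    right_near = right_gap is not None and right_gap < utr_cutoff

    if left_near and right_near:
        return Classification(
            region_id=region.id,
            category="operon_element",
            gene_ids=(left.id, right.id),
            distances=(left_gap, right_gap),
        )
    if left_near or right_near:
        # a left/right distance tie cannot reach here: both-near is operon
        if right_near:
            gene, gap, side = right, right_gap, _utr_side(right, True)
        else:
            gene, gap, side = left, left_gap, _utr_side(left, False)
        return Classification(
            region_id=region.id,
            category=side,
            gene_ids=(gene.id,),
            distances=(gap,),
        )

    opposite = index.overlapping(
        "-" if region.strand == "+" else "+", region.start, region.end
    )
    if opposite:
        return Classification(
            region_id=region.id,
            category="antisense",
            gene_ids=tuple(g.id for g in opposite),
            distances=tuple(0 for _ in opposite),
        )
    return Classification(region_id=region.id, category="novel")


def classify_regions(
    regions: Sequence[Region],
    genes: Sequence[GeneFeature],
    utr_cutoff: int = 100,
) -> list[Classification]:
    index = AnnotationIndex(genes)
    return [classify_region(r, index, utr_cutoff) for r in regions]


def filter_antisense(
    classified: Sequence[tuple[Region, Classification]],
) -> tuple[list[tuple[Region, Classification]], int]:
    """Drop antisense regions (validity not establishable); count the removals."""
    kept = [(r, c) for r, c in classified if c.category != "antisense"]
    removed = len(classified) - len(kept)
    if removed:
        log.info("removed %d possible antisense regions", removed)
    return kept, removed


def summarize(
    diff_classified: Sequence[Classification],
    similar_classified: Sequence[Classification],
    genes: Sequence[GeneFeature],
) -> tuple[pd.DataFrame, dict]:
    """Category count table plus gene-touch bookkeeping.

    The operon-element row adds, for every touching region spanning k >= 2
    same-strand genes, its k-1 inter-gene parts (a region across adjacent
    transcripts identifies a potential operon).  Genes touched are counted
    once each, with the ncRNA subtotal alongside.
    """
    gene_kind = {g.id: g.kind for g in genes}
    table = pd.DataFrame(
        0, index=list(CATEGORIES), columns=["differential", "similar"]
    )
    extras: dict = {}
    for col, classified in (
        ("differential", diff_classified),
        ("similar", similar_classified),
    ):
        touched: set[str] = set()
        operon_parts = 0
        for c in classified:
            table.loc[c.category, col] += 1
            if c.category == "touching":
                touched.update(c.gene_ids)
                if len(c.gene_ids) >= 2:
                    operon_parts += len(c.gene_ids) - 1
        table.loc["operon_element", col] += operon_parts
        extras[col] = {
            "genes_touched": len(touched),
            "ncRNAs_touched": sum(
                1 for gid in touched if gene_kind.get(gid) == "ncRNA"
            ),
            "operon_parts_from_spanning_regions": operon_parts,
        }
    return table, extras
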