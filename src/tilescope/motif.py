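"""Ada-regulon promoter scan.

The methylated Ada transcriptional activator recognises two short promoter
elements: box A (``AAT``) and box B (``GCAA``), canonically separated by a
6 nt spacer.  This module searches the 200 nt upstream of transcript start
sites for perfect A and B boxes at spacers of 5-7 nt and compares the
occurrence rate between gene groups (e.g. differentially vs similarly
expressed) with a two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq
from scipy.stats import fisher_exact

log = logging.getLogger(__name__)

BOX_A = "AAT"
BOX_B = "GCAA"


@dataclass(frozen=True)
class AdaBoxMatch:
    """One box A + spacer + box B hit in an upstream window.

    ``offset`` is the 0-based position of box A within the upstream sequence
    (read 5'->3' towards the start site); ``upstream_distance`` counts the
    nucleotides between the last base of box B and the start site (0 means
    box B abuts the start site).  The matched sequence is
    boxA + spacer + boxB, 12-14 nt.
    """

    gene_id: str
    upstream_distance: int
    spacer: int
    sequence: str
    start_site: int
    strand: str
    source: str = "annotated"  # annotated | detected
    offset: int = 0

    def __post_init__(self) -> None:
        if not (self.sequence.startswith(BOX_A) and self.sequence.endswith(BOX_B)):
            raise ValueError(f"malformed match sequence {self.sequence!r}")
        if self.spacer != len(self.sequence) - len(BOX_A) - len(BOX_B):
            raise ValueError("spacer inconsistent with matched sequence length")


def find_ada_boxes(
    seq: str, spacer_min: int = 5, spacer_max: int = 7
) -> list[tuple[int, int, str]]:
    """All (offset, spacer, matched sequence) box A/B hits in ``seq``.

    Every position with ``AAT`` at ``i`` and ``GCAA`` at ``i + 3 + s`` for
    some spacer ``s`` yields one hit per (i, s); overlapping hits are all
    reported.  ``N`` never matches.
    """
    if spacer_min < 0 or spacer_max < spacer_min:
        raise ValueError("invalid spacer range")
    seq = seq.upper()
    hits: list[tuple[int, int, str]] = []
    la, lb = len(BOX_A), len(BOX_B)
    for i in range(len(seq) - la - lb - spacer_min + 1):
        if seq[i : i + la] != BOX_A:
            continue
        for s in range(spacer_min, spacer_max + 1):
            j = i + la + s
            if seq[j : j + lb] == BOX_B:
                hits.append((i, s, seq[i : j + lb]))
    return hits


def extract_upstream(genome: str, start: int, end: int, strand: str, window: int = 200) -> str:
    """The ``window`` nt upstream of a transcript start site, read 5'->3'.

    For a + feature this is the genomic window ending immediately before
    ``start``; for a - feature, the window beginning immediately after
    ``end``, reverse-complemented.  Truncated (and logged) near genome ends.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = len(genome)
    if not (1 <= start <= end <= n):
        raise ValueError(f"feature [{start}, {end}] outside genome of {n} nt")
    if strand == "+":
        lo = max(1, start - window)
        seq = genome[lo - 1 : start - 1]
    elif strand == "-":
        hi = min(n, end + window)
        seq = str(Seq(genome[end:hi]).reverse_complement())
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if len(seq) < window:
        log.warning(
            "upstream window truncated to %d nt at genome end (strand %s)",
            len(seq),
            strand,
        )
    return seq


def start_site(start: int, end: int, strand: str) -> int:
    """Genomic position of a feature's 5'-most base on its strand."""
    return start if strand == "+" else end


def scan_genes(
    features: Iterable[tuple[str, int, int, str]],
    genome: str,
    groups: Mapping[str, str] | None = None,
    window: int = 200,
    spacer_min: int = 5,
    spacer_max: int = 7,
    source: str = "annotated",
    anchor: str = "boxB",
) -> tuple[list[AdaBoxMatch], pd.DataFrame, dict]:
    """Scan upstream windows of features ``(id, start, end, strand)``.

    Returns all matches, a tidy per-match table, and per-group statistics:
    the fraction of features with at least one hit per group and a two-sided
    Fisher exact p-value comparing the first two groups (exploratory,
    reported, never thresholded).

    ``anchor`` selects the upstream-distance convention: ``"boxB"`` counts
    the nucleotides between the last base of box B and the start site,
    ``"boxA"`` between the first base of box A and the start site.
    """
    if anchor not in ("boxA", "boxB"):
        raise ValueError(f"unknown anchor {anchor!r}")
    matches: list[AdaBoxMatch] = []
    with_hit: dict[str, set[str]] = {}
    totals: dict[str, int] = {}
    for fid, start, end, strand in features:
        group = groups.get(fid, "all") if groups is not None else "all"
        totals[group] = totals.get(group, 0) + 1
        upstream = extract_upstream(genome, start, end, strand, window)
        site = start_site(start, end, strand)
        for offset, spacer, seq in find_ada_boxes(upstream, spacer_min, spacer_max):
            if anchor == "boxB":
                distance = len(upstream) - (offset + len(BOX_A) + spacer + len(BOX_B))
            else:
                distance = len(upstream) - offset
            matches.append(
                AdaBoxMatch(
                    gene_id=fid,
                    upstream_distance=distance,
                    spacer=spacer,
                    sequence=seq,
                    start_site=site,
                    strand=strand,
                    source=source,
                    offset=offset,
                )
            )
            with_hit.setdefault(group, set()).add(fid)

    table = pd.DataFrame(
        [
            (
                m.upstream_distance,
                m.spacer,
                m.sequence,
                m.gene_id,
                m.start_site,
                m.strand,
                m.source,
            )
            for m in matches
        ],
        columns=[
            "upstream_distance",
            "spacer",
            "sequence",
            "gene",
            "start_site",
            "strand",
            "source",
        ],
    )

    stats: dict = {"groups": {}}
    for group, total in totals.items():
        k = len(with_hit.get(group, set()))
        stats["groups"][group] = {
            "n": total,
            "with_match": k,
            "rate": k / total if total else float("nan"),
        }
    group_names = sorted(totals)
    if len(group_names) >= 2:
        a, b = group_names[0], group_names[1]
        ka = len(with_hit.get(a, set()))
        kb = len(with_hit.get(b, set()))
        _, p = fisher_exact(
            [[ka, totals[a] - ka], [kb, totals[b] - kb]], alternative="two-sided"
        )
        stats["fisher_p"] = float(p)
        stats["compared"] = (a, b)
    return matches, table, stats
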