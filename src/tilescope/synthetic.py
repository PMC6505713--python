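"""Synthetic tiling-array fixtures with a known truth set.

Generates a small artificial replicon, a gene annotation, a selective tiling
layout (dense probe coverage of coding regions, fine-stepped tiling of
intergenic space on both strands) and replicate log2 probe intensities, so
every downstream stage is testable without any external download.

The defaults emulate the study design the pipeline targets: 19 probes per
coding gene, 14 nt intergenic tiling step, 25 nt probes, five replicates per
condition, a log2 background of 7.5 (below the 9.0 detection floor),
expressed levels in [10, 14] and spiked log2 shifts of at least 1.5 for
differential transcripts, with i.i.d. Gaussian probe noise (sd 0.3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from intervaltree import IntervalTree

from .types import CONDITIONS, GeneFeature, IntensityMatrix, Probe

log = logging.getLogger(__name__)

#: Truth statuses a transcript can take.
STATUSES = (
    "expressed_both",
    "expressed_ref_only",
    "expressed_treated_only",
    "silent",
)

DEFAULT_BACKGROUND = 7.5
DEFAULT_NOISE_SD = 0.3
DEFAULT_PROBE_LEN = 25
DEFAULT_INTERGENIC_STEP = 14
DEFAULT_PROBES_PER_GENE = 19
DEFAULT_SHIFT_RANGE = (1.5, 2.5)


class NovelInterval(NamedTuple):
    """A truly transcribed but unannotated interval."""

    start: int
    end: int
    strand: str


class InfeasiblePackingError(ValueError):
    """Requested features cannot fit in the genome without overlap."""


@dataclass
class TranscriptTruth:
    """Ground truth for one transcript (annotated gene or novel interval)."""

    id: str
    start: int
    end: int
    strand: str
    annotated: bool
    status: str
    level_reference: float
    level_treated: float

    @property
    def shift(self) -> float:
        """True log2 shift, treated minus reference."""
        return self.level_treated - self.level_reference


@dataclass
class TruthSet:
    """Everything the simulator decided, for downstream bookkeeping."""

    transcripts: list[TranscriptTruth]
    background_mean: float
    noise_sd: float
    seed: int

    def differential(self, min_shift: float = 0.0) -> list[TranscriptTruth]:
        """Transcripts with a true level change between conditions.

        Includes transcripts expressed in only one condition (their shift is
        the distance from background), excludes silent ones.
        """
        return [
            t
            for t in self.transcripts
            if t.status != "silent" and abs(t.shift) > max(min_shift, 0.0)
        ]

    def null(self) -> list[TranscriptTruth]:
        """Transcripts expressed in both conditions with zero true shift."""
        return [
            t
            for t in self.transcripts
            if t.status == "expressed_both" and t.shift == 0.0
        ]

    def by_id(self) -> dict[str, TranscriptTruth]:
        return {t.id: t for t in self.transcripts}


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    length: int,
    n_genes: int,
    n_novel: int,
    seed: int,
    gene_length: tuple[int, int] = (300, 1000),
    novel_length: tuple[int, int] = (60, 250),
    min_gap: int = 150,
    ncrna_fraction: float = 0.15,
) -> tuple[str, list[GeneFeature], list[NovelInterval]]:
    """Generate a random replicon with non-overlapping genes and novel intervals.

    Features (genes and truly novel transcribed intervals) are packed left to
    right with random gaps of at least ``min_gap`` nt, so no two features
    overlap on either strand and novel intervals are intergenic by
    construction.  Gene lengths default to U(300, 1000) nt so that the
    default 19 evenly spaced probes per gene are at most ~54 nt apart.
    Coordinates are 1-based inclusive; identical seeds give byte-identical
    output.
    """
    if length < 5000:
        raise ValueError("genome length must be at least 5000 nt")
    rng = np.random.default_rng(seed)

    n_feat = n_genes + n_novel
    gene_lens = rng.integers(gene_length[0], gene_length[1] + 1, size=n_genes)
    novel_lens = rng.integers(novel_length[0], novel_length[1] + 1, size=n_novel)
    is_novel = np.array([False] * n_genes + [True] * n_novel)
    lens = np.concatenate([gene_lens, novel_lens]).astype(int)
    order = rng.permutation(n_feat)
    lens, is_novel = lens[order], is_novel[order]

    slack = length - int(lens.sum()) - (n_feat + 1) * min_gap
    if slack < 0:
        raise InfeasiblePackingError(
            f"cannot place {n_genes} genes and {n_novel} novel intervals "
            f"of total length {int(lens.sum())} nt plus {min_gap} nt gaps "
            f"in a {length} nt genome"
        )
    extra = (
        rng.multinomial(slack, np.full(n_feat + 1, 1.0 / (n_feat + 1)))
        if n_feat
        else np.array([slack])
    )
    gaps = extra + min_gap

    genes: list[GeneFeature] = []
    novels: list[NovelInterval] = []
    pos = 0
    gi = ni = 0
    for k in range(n_feat):
        pos += int(gaps[k])
        start = pos + 1
        end = pos + int(lens[k])
        strand = "+" if rng.random() < 0.5 else "-"
        if is_novel[k]:
            ni += 1
            novels.append(NovelInterval(start, end, strand))
        else:
            gi += 1
            kind = "ncRNA" if rng.random() < ncrna_fraction else "protein_coding"
            genes.append(
                GeneFeature(
                    id=f"gene{gi:04d}",
                    name=f"g{gi:04d}",
                    start=start,
                    end=end,
                    strand=strand,
                    kind=kind,
                )
            )
        pos = end

    seq = "".join(rng.choice(list("ACGT"), size=length))
    return seq, genes, novels


# ---------------------------------------------------------------------------
# expression truth
# ---------------------------------------------------------------------------

def assign_expression(
    genes: Sequence[GeneFeature],
    novels: Sequence[NovelInterval],
    seed: int,
    background_mean: float = DEFAULT_BACKGROUND,
    noise_sd: float = DEFAULT_NOISE_SD,
    frac_differential: float = 0.3,
    frac_ref_only: float = 0.05,
    frac_treated_only: float = 0.05,
    frac_silent: float = 0.1,
    novel_differential_frac: float = 0.5,
    shift_range: tuple[float, float] = DEFAULT_SHIFT_RANGE,
    level_range: tuple[float, float] = (10.0, 14.0),
) -> TruthSet:
    """Assign a true status and per-condition log2 levels to every transcript.

    Differential transcripts get a base level in the lower half of
    ``level_range`` for their low condition and a spike of U(``shift_range``)
    on top for the high condition, so both conditions stay above the 9.0
    detection floor and every true |shift| clears the 0.5 fold-change
    threshold by at least 1.0 log2.  Single-condition transcripts sit at
    background in the silent condition.
    """
    if not (shift_range[0] >= 1.0):
        raise ValueError("differential shifts must be at least 1.0 log2")
    rng = np.random.default_rng(seed)
    lo, hi = level_range

    def _levels(status: str, make_shift: bool) -> tuple[float, float]:
        if status == "silent":
            return background_mean, background_mean
        if status == "expressed_ref_only":
            return float(rng.uniform(lo, hi)), background_mean
        if status == "expressed_treated_only":
            return background_mean, float(rng.uniform(lo, hi))
        # expressed_both
        if make_shift:
            base = float(rng.uniform(lo, hi - shift_range[1]))
            shift = float(rng.uniform(*shift_range))
            up = rng.random() < 0.5
            return (base, base + shift) if up else (base + shift, base)
        level = float(rng.uniform(lo, hi))
        return level, level

    transcripts: list[TranscriptTruth] = []
    probs = np.array(
        [frac_differential, frac_ref_only, frac_treated_only, frac_silent]
    )
    if probs.sum() > 1.0:
        raise ValueError("status fractions exceed 1")
    for g in genes:
        u = rng.random()
        edges = np.cumsum(probs)
        if u < edges[0]:
            status, shifted = "expressed_both", True
        elif u < edges[1]:
            status, shifted = "expressed_ref_only", False
        elif u < edges[2]:
            status, shifted = "expressed_treated_only", False
        elif u < edges[3]:
            status, shifted = "silent", False
        else:
            status, shifted = "expressed_both", False
        lr, lt = _levels(status, shifted)
        transcripts.append(
            TranscriptTruth(
                id=g.id,
                start=g.start,
                end=g.end,
                strand=g.strand,
                annotated=True,
                status=status,
                level_reference=lr,
                level_treated=lt,
            )
        )
    for i, nv in enumerate(novels, start=1):
        shifted = rng.random() < novel_differential_frac
        lr, lt = _levels("expressed_both", shifted)
        transcripts.append(
            TranscriptTruth(
                id=f"novel{i:04d}",
                start=nv.start,
                end=nv.end,
                strand=nv.strand,
                annotated=False,
                status="expressed_both",
                level_reference=lr,
                level_treated=lt,
            )
        )
    return TruthSet(
        transcripts=transcripts,
        background_mean=background_mean,
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tiling design
# ---------------------------------------------------------------------------

def design_tiling(
    genes: Sequence[GeneFeature],
    genome_length: int,
    probes_per_gene: int = DEFAULT_PROBES_PER_GENE,
    intergenic_step: int = DEFAULT_INTERGENIC_STEP,
    probe_len: int = DEFAULT_PROBE_LEN,
) -> list[Probe]:
    """Selective tiling: dense gene coverage plus stepped intergenic tiling.

    Each gene gets exactly ``probes_per_gene`` evenly spaced probes on its
    own strand (a gene shorter than ``probe_len`` gets one centred probe,
    logged).  Intergenic space — positions covered by no gene on either
    strand — is tiled on both strands at ``intergenic_step``.  Probes are
    sorted by (strand, start) and never extend past the genome end.
    """
    if probes_per_gene < 2:
        raise ValueError("probes_per_gene must be >= 2")
    if intergenic_step < 1:
        raise ValueError("intergenic_step must be >= 1")
    if probe_len < 10:
        raise ValueError("probe_len must be >= 10")

    placements: list[tuple[str, int, str]] = []  # (strand, start, kind)
    for g in genes:
        if g.length < probe_len:
            centre = (g.start + g.end) // 2
            start = max(1, min(centre - probe_len // 2, genome_length - probe_len + 1))
            log.warning(
                "gene %s (%d nt) shorter than probe length %d: single centred probe",
                g.id,
                g.length,
                probe_len,
            )
            placements.append((g.strand, start, "genic"))
            continue
        starts = np.linspace(g.start, g.end - probe_len + 1, probes_per_gene)
        for s in np.rint(starts).astype(int):
            placements.append((g.strand, int(s), "genic"))

    # intergenic gaps: complement of gene spans on either strand
    from .intervals import merge_intervals

    occupied = merge_intervals([(g.start, g.end) for g in genes]) if genes else []
    gaps: list[tuple[int, int]] = []
    prev_end = 0
    for s, e in occupied:
        if s - 1 > prev_end:
            gaps.append((prev_end + 1, s - 1))
        prev_end = max(prev_end, e)
    if prev_end < genome_length:
        gaps.append((prev_end + 1, genome_length))

    for gs, ge in gaps:
        if ge - gs + 1 < probe_len:
            continue
        start = gs
        while start + probe_len - 1 <= ge:
            placements.append(("+", start, "intergenic"))
            placements.append(("-", start, "intergenic"))
            start += intergenic_step

    placements.sort(key=lambda p: (p[0], p[1]))
    probes = [
        Probe(
            id=f"probe_{i:06d}",
            start=start,
            end=start + probe_len - 1,
            strand=strand,
            kind=kind,
        )
        for i, (strand, start, kind) in enumerate(placements, start=1)
    ]
    assert all(p.end <= genome_length for p in probes)
    return probes


def undetectable_transcripts(
    layout: Sequence[Probe], truth: TruthSet
) -> list[str]:
    """Truth transcripts with no probe midpoint inside them (logged)."""
    trees = {"+": IntervalTree(), "-": IntervalTree()}
    for i, t in enumerate(truth.transcripts):
        trees[t.strand][t.start : t.end + 1] = i
    hit = set()
    for p in layout:
        for iv in trees[p.strand][p.midpoint]:
            hit.add(iv.data)
    missed = [
        t.id for i, t in enumerate(truth.transcripts) if i not in hit
    ]
    for tid in missed:
        log.warning("truth transcript %s is undetectable: no probe targets it", tid)
    return missed


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def simulate_intensities(
    layout: Sequence[Probe],
    truth: TruthSet,
    n_replicates: int = 5,
    seed: int | None = None,
) -> IntensityMatrix:
    """Simulate replicate log2 intensities from the truth set.

    A probe reads the transcript level of its condition if its midpoint lies
    inside a transcribed truth interval on the probe's strand, otherwise the
    background mean; i.i.d. Gaussian noise (``truth.noise_sd``) is added to
    every probe x sample cell.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per condition")
    if truth.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if truth.background_mean >= 9.0:
        raise ValueError("background_mean must sit below the 9.0 detection floor")
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    trees = {"+": IntervalTree(), "-": IntervalTree()}
    for t in truth.transcripts:
        trees[t.strand][t.start : t.end + 1] = t

    n_probes = len(layout)
    levels = np.full((n_probes, 2), truth.background_mean)
    for i, p in enumerate(layout):
        hits = trees[p.strand][p.midpoint]
        if hits:
            t = min(hits, key=lambda iv: iv.begin).data
            levels[i, 0] = t.level_reference
            levels[i, 1] = t.level_treated

    noise = rng.normal(0.0, truth.noise_sd, size=(n_probes, 2 * n_replicates))
    values = np.empty((n_probes, 2 * n_replicates))
    values[:, :n_replicates] = levels[:, [0]] + noise[:, :n_replicates]
    values[:, n_replicates:] = levels[:, [1]] + noise[:, n_replicates:]

    conditions = [CONDITIONS[0]] * n_replicates + [CONDITIONS[1]] * n_replicates
    replicates = list(range(1, n_replicates + 1)) * 2
    return IntensityMatrix(
        probe_ids=[p.id for p in layout],
        values=values,
        conditions=conditions,
        replicates=replicates,
    )


# ---------------------------------------------------------------------------
# truth table I/O
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            (
                t.id,
                t.start,
                t.end,
                t.strand,
                int(t.annotated),
                t.status,
                t.level_reference,
                t.level_treated,
                t.shift,
            )
            for t in truth.transcripts
        ],
        columns=[
            "id",
            "start",
            "end",
            "strand",
            "annotated",
            "status",
            "level_reference",
            "level_treated",
            "shift",
        ],
    )
    for col in ("level_reference", "level_treated", "shift"):
        df[col] = df[col].map(repr)  # lossless float round trip
    with open(path, "w") as fh:
        fh.write(
            f"# background_mean={truth.background_mean}\t"
            f"noise_sd={truth.noise_sd}\tseed={truth.seed}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_truth(path) -> TruthSet:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline().lstrip("# ").strip()
        meta = dict(item.split("=") for item in header.split("\t"))
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    transcripts = [
        TranscriptTruth(
            id=row.id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            annotated=bool(row.annotated),
            status=row.status,
            level_reference=float(row.level_reference),
            level_treated=float(row.level_treated),
        )
        for row in df.itertuples()
    ]
    return TruthSet(
        transcripts=transcripts,
        background_mean=float(meta["background_mean"]),
        noise_sd=float(meta["noise_sd"]),
        seed=int(meta["seed"]),
    )
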