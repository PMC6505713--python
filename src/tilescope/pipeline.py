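"""End-to-end orchestration: fixture generation, stage execution, summary.

``make_fixture`` writes a complete synthetic input bundle (genome FASTA,
GFF3 + BED annotation, probe layout TSV, intensity TSV, truth TSV);
``run_pipeline`` executes io -> annotation DE -> segmentation ->
classification (antisense filtered) -> motif scan -> optional
meta-comparison, writing one TSV per stage plus a JSON summary and a
MANIFEST.  Every number in the summary is re-derivable from the stage TSVs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotation_de, classification, io, motif, segmentation, synthetic
from .compare import PredictionSet, classify_predictions
from .types import GeneFeature, Region

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All paths and thresholds of a pipeline run.

    Threshold defaults are the analysis constants the pipeline is built
    around: 9.0 log2 detection floor, P > 0.95, |log2FC| > 0.5, 25 nt
    minimum differential length, >35 nt minimum expressed length, <100 nt
    UTR/operon cutoff, 200 nt promoter window with 5-7 nt box spacers.
    """

    genome: str = "genome.fasta"
    annotation: str = "annotation.gff3"
    annotation_dialect: str = "gff3"
    layout: str = "layout.tsv"
    intensities: str = "intensities.tsv"
    outdir: str = "results"
    predictions: dict[str, str] = field(default_factory=dict)
    floor: float = 9.0
    p_threshold: float = 0.95
    fc_threshold: float = 0.5
    min_de_length: int = 25
    min_expr_length: int = 35
    utr_cutoff: int = 100
    motif_window: int = 200
    spacer_min: int = 5
    spacer_max: int = 7
    penalty: float = segmentation.DEFAULT_PENALTY
    max_gap: int = segmentation.DEFAULT_MAX_GAP
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "floor",
            "p_threshold",
            "fc_threshold",
            "min_de_length",
            "min_expr_length",
            "utr_cutoff",
            "motif_window",
            "penalty",
            "max_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def make_fixture(
    outdir: str | Path,
    seed: int = 0,
    genome_length: int = 60_000,
    n_genes: int = 20,
    n_novel: int = 8,
    n_replicates: int = 5,
    background_mean: float = synthetic.DEFAULT_BACKGROUND,
    noise_sd: float = synthetic.DEFAULT_NOISE_SD,
    probes_per_gene: int = synthetic.DEFAULT_PROBES_PER_GENE,
    intergenic_step: int = synthetic.DEFAULT_INTERGENIC_STEP,
    probe_len: int = synthetic.DEFAULT_PROBE_LEN,
    **expression_kwargs,
) -> tuple[PipelineConfig, synthetic.TruthSet]:
    """Generate and write a complete synthetic input bundle.

    Returns a ready-to-run config pointing at the written files, plus the
    truth set.  Deterministic given the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seq, genes, novels = synthetic.simulate_genome(
        genome_length, n_genes, n_novel, seed=seed
    )
    truth = synthetic.assign_expression(
        genes,
        novels,
        seed=seed + 1,
        background_mean=background_mean,
        noise_sd=noise_sd,
        **expression_kwargs,
    )
    layout = synthetic.design_tiling(
        genes,
        genome_length,
        probes_per_gene=probes_per_gene,
        intergenic_step=intergenic_step,
        probe_len=probe_len,
    )
    synthetic.undetectable_transcripts(layout, truth)
    matrix = synthetic.simulate_intensities(
        layout, truth, n_replicates=n_replicates, seed=seed + 2
    )

    io.write_genome_fasta(seq, outdir / "genome.fasta")
    io.write_annotation(genes, outdir / "annotation.gff3", dialect="gff3")
    io.write_annotation(genes, outdir / "annotation.bed", dialect="bed6")
    io.write_probe_layout(layout, outdir / "layout.tsv")
    io.write_intensity_table(matrix, outdir / "intensities.tsv")
    synthetic.write_truth(truth, outdir / "truth.tsv")

    config = PipelineConfig(
        genome=str(outdir / "genome.fasta"),
        annotation=str(outdir / "annotation.gff3"),
        layout=str(outdir / "layout.tsv"),
        intensities=str(outdir / "intensities.tsv"),
        outdir=str(outdir / "results"),
        seed=seed,
    )
    config.to_yaml(outdir / "config.yaml")
    return config, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the summary dict (also written as JSON).

    Any stage error aborts with the stage name; partial outputs are retained
    and the MANIFEST marks the run incomplete.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"complete": False, "stages": []}
    summary: dict = {}

    def _stage(name):
        manifest["stages"].append(name)
        log.info("stage %s", name)

    try:
        _stage("io")
        try:
            genome = io.read_genome_fasta(config.genome)
            genes = io.read_annotation(config.annotation, config.annotation_dialect)
            layout = io.read_probe_layout(config.layout)
            matrix = io.read_intensity_table(config.intensities, layout)
        except (OSError, ValueError) as exc:
            raise PipelineError("io", str(exc)) from exc
        order = matrix.rows([p.id for p in layout])
        matrix.values = matrix.values[order]
        matrix.probe_ids = [p.id for p in layout]
        matrix._row_of = {p: i for i, p in enumerate(matrix.probe_ids)}

        _stage("annotation_de")
        calls, de_summary, untestable = annotation_de.call_annotated(
            genes,
            layout,
            matrix,
            p_threshold=config.p_threshold,
            fc_threshold=config.fc_threshold,
            floor=config.floor,
        )
        annotation_de.calls_to_frame(calls).to_csv(
            outdir / "annotated_de.tsv", sep="\t", index=False
        )
        summary["annotation_de"] = de_summary
        summary["untestable_genes"] = untestable

        _stage("segmentation")
        regions = segmentation.segment_genome(
            layout,
            matrix,
            penalty=config.penalty,
            max_gap=config.max_gap,
            floor=config.floor,
        )
        differential, similar = segmentation.call_regions(
            regions,
            p_threshold=config.p_threshold,
            fc_threshold=config.fc_threshold,
            min_de_length=config.min_de_length,
            min_expr_length=config.min_expr_length,
        )
        io.write_regions(differential, outdir / "regions_differential.tsv")
        io.write_regions(similar, outdir / "regions_similar.tsv")
        expressed_nt = {
            c: segmentation.count_expressed_nucleotides(
                list(differential) + list(similar), c
            )
            for c in ("reference", "treated")
        }
        summary["segmentation"] = {
            "segments_total": len(regions),
            "differential_regions": len(differential),
            "similar_regions": len(similar),
            "expressed_nt": expressed_nt,
            "expressed_nt_ratio_treated_vs_reference": (
                expressed_nt["treated"] / expressed_nt["reference"]
                if expressed_nt["reference"]
                else float("nan")
            ),
        }

        _stage("classification")
        cls_summaries = {}
        filtered: dict[str, list[Region]] = {}
        classified_kept: dict[str, list[classification.Classification]] = {}
        for label, regs in (("differential", differential), ("similar", similar)):
            cls = classification.classify_regions(regs, genes, config.utr_cutoff)
            kept, removed = classification.filter_antisense(list(zip(regs, cls)))
            filtered[label] = [r for r, _ in kept]
            classified_kept[label] = [c for _, c in kept]
            import pandas as pd

            pd.DataFrame(
                [
                    (
                        c.region_id,
                        c.category,
                        ",".join(c.gene_ids),
                        ",".join(str(d) for d in c.distances),
                    )
                    for c in cls
                ],
                columns=["region_id", "category", "gene_ids", "distances"],
            ).to_csv(outdir / f"classification_{label}.tsv", sep="\t", index=False)
            cls_summaries[label] = {"antisense_removed": removed}
        table, extras = classification.summarize(
            classified_kept["differential"], classified_kept["similar"], genes
        )
        table.to_csv(outdir / "classification_summary.tsv", sep="\t")
        summary["classification"] = {
            "counts": {
                col: {cat: int(table.loc[cat, col]) for cat in table.index}
                for col in table.columns
            },
            "genes_touched": extras,
            "antisense_removed": {
                label: cls_summaries[label]["antisense_removed"]
                for label in cls_summaries
            },
        }

        _stage("motif_scan")
        groups = {}
        de_genes = []
        gene_by_id = {g.id: g for g in genes}
        for c in calls:
            if c.status in ("up", "down", "absent_treated_only", "absent_reference_only"):
                groups[c.feature_id] = "differential"
            elif c.status == "similar":
                groups[c.feature_id] = "similar"
            else:
                continue
            g = gene_by_id[c.feature_id]
            de_genes.append((g.id, g.start, g.end, g.strand))
        _, motif_table, motif_stats = motif.scan_genes(
            de_genes,
            genome,
            groups=groups,
            window=config.motif_window,
            spacer_min=config.spacer_min,
            spacer_max=config.spacer_max,
        )
        motif_table.to_csv(outdir / "adabox.tsv", sep="\t", index=False)
        summary["motif_scan"] = motif_stats

        if config.predictions:
            _stage("meta_compare")
            compare_summary = {}
            for name, path in sorted(config.predictions.items()):
                feats = io.read_annotation(path, "bed6")
                pset = PredictionSet(
                    name=name,
                    intervals=[(f.start, f.end, f.strand) for f in feats],
                )
                counts, _ = classify_predictions(
                    pset, filtered["differential"], filtered["similar"]
                )
                compare_summary[name] = counts
            summary["meta_compare"] = compare_summary

        manifest["complete"] = True
    finally:
        summary_path = outdir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary


def recovery_metrics(
    differential_regions: list[Region],
    truth: synthetic.TruthSet,
    layout,
    min_shift: float = 0.0,
    truth_overlap_frac: float = 0.5,
    region_overlap_frac: float = 0.5,
) -> dict:
    """Sensitivity/precision of differential-region recovery vs the truth set.

    A detectable differential truth transcript (one with at least one
    targeting probe) is recovered when a same-strand differential region
    covers at least ``truth_overlap_frac`` of it.  A differential region is
    a true positive when at least ``region_overlap_frac`` of the region lies
    inside differential truth transcripts on its strand.
    """
    from .intervals import intersect_merged, merge_intervals, overlap_length

    undetectable = set(synthetic.undetectable_transcripts(layout, truth))
    diff_truth = [
        t for t in truth.differential(min_shift) if t.id not in undetectable
    ]
    truth_by_strand = {
        s: merge_intervals(
            [(t.start, t.end) for t in diff_truth if t.strand == s] or []
        )
        for s in ("+", "-")
    }

    recovered = 0
    for t in diff_truth:
        best = 0
        for r in differential_regions:
            if r.strand != t.strand:
                continue
            best = max(best, overlap_length((t.start, t.end), (r.start, r.end)))
        if best >= truth_overlap_frac * (t.end - t.start + 1):
            recovered += 1

    true_pos = 0
    for r in differential_regions:
        merged = truth_by_strand[r.strand]
        inside = sum(
            overlap_length((r.start, r.end), iv) for iv in merged
        )
        if inside >= region_overlap_frac * r.length:
            true_pos += 1

    n_regions = len(differential_regions)
    return {
        "detectable_differential_truth": len(diff_truth),
        "recovered": recovered,
        "sensitivity": recovered / len(diff_truth) if diff_truth else float("nan"),
        "differential_regions": n_regions,
        "true_positive_regions": true_pos,
        "precision": true_pos / n_regions if n_regions else float("nan"),
    }
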