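"""Readers and writers for every on-disk format the pipeline touches.

Internal coordinates are 1-based inclusive everywhere; BED6's 0-based
half-open convention is converted exactly at this boundary, so that
``bed_end - bed_start == end - start + 1`` always holds.  The pipeline is
single-replicon: multi-record FASTA files are rejected rather than
half-supported.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .types import GeneFeature, IntensityMatrix, Probe, Region

log = logging.getLogger(__name__)

_VALID_BASES = set("ACGTN")

#: Default sequence name written into FASTA/GFF3/BED output.
DEFAULT_SEQID = "replicon"


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> str:
    """Read a single-record FASTA into an uppercase ACGTN string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if len(records) > 1:
        raise ValueError("multi-record FASTA not supported (single replicon only)")
    seq = str(records[0].seq).upper()
    if not seq:
        raise ValueError(f"empty sequence in {path}")
    for i, base in enumerate(seq):
        if base not in _VALID_BASES:
            raise ValueError(
                f"invalid character {base!r} at position {i + 1} in {path}"
            )
    return seq


def write_genome_fasta(seq: str, path: str | Path, seqid: str = DEFAULT_SEQID) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seqid}\n")
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_annotation(path: str | Path, dialect: str = "gff3") -> list[GeneFeature]:
    """Read gene features from GFF3 or BED6, sorted by start.

    GFF3 feature kinds are taken from the type column; BED features default
    to ``protein_coding``.  BED's half-open 0-based coordinates are converted
    to 1-based inclusive.
    """
    if dialect == "gff3":
        genes = _read_gff3(path)
    elif dialect == "bed6":
        genes = _read_bed6(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return sorted(genes, key=lambda g: (g.start, g.end, g.id))


def _read_gff3(path: str | Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for f in db.all_features():
        fid = f.attributes.get("ID", [f.id])[0]
        name = f.attributes.get("Name", [fid])[0]
        if f.start > f.end:
            raise ValueError(f"start > end for feature {fid} in {path}")
        genes.append(
            GeneFeature(
                id=fid,
                name=name,
                start=int(f.start),
                end=int(f.end),
                strand=f.strand,
                kind=f.featuretype,
            )
        )
    return genes


def _read_bed6(path: str | Path) -> list[GeneFeature]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 needs 6 columns")
            _, bed_start, bed_end, name, _score, strand = fields[:6]
            start = int(bed_start) + 1  # half-open 0-based -> inclusive 1-based
            end = int(bed_end)
            if start > end:
                raise ValueError(f"{path}:{lineno}: start > end after conversion")
            genes.append(
                GeneFeature(id=name, name=name, start=start, end=end, strand=strand)
            )
    return genes


def write_annotation(
    genes: Sequence[GeneFeature],
    path: str | Path,
    dialect: str = "gff3",
    seqid: str = DEFAULT_SEQID,
) -> None:
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={g.id};Name={g.name}"
                fh.write(
                    f"{seqid}\ttilescope\t{g.kind}\t{g.start}\t{g.end}"
                    f"\t.\t{g.strand}\t.\t{attrs}\n"
                )
        elif dialect == "bed6":
            for g in genes:
                fh.write(
                    f"{seqid}\t{g.start - 1}\t{g.end}\t{g.id}\t0\t{g.strand}\n"
                )
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# probe layout
# ---------------------------------------------------------------------------

_LAYOUT_COLS = ["probe_id", "start", "end", "strand", "kind"]


def write_probe_layout(layout: Sequence[Probe], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.id, p.start, p.end, p.strand, p.kind) for p in layout],
        columns=_LAYOUT_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_probe_layout(path: str | Path) -> list[Probe]:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    missing = [c for c in _LAYOUT_COLS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"probe layout {path} missing columns {missing}")
    if "kind" not in df.columns:
        df["kind"] = "intergenic"
    return [
        Probe(
            id=row.probe_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            kind=row.kind,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def write_intensity_table(matrix: IntensityMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


def read_intensity_table(
    path: str | Path, layout: Sequence[Probe] | None = None
) -> IntensityMatrix:
    """Read a probes x samples log2 table; no imputation, missing values error."""
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str}, float_precision="round_trip"
    )
    if "probe_id" not in df.columns:
        raise ValueError(f"intensity table {path} has no 'probe_id' column")
    sample_cols = [c for c in df.columns if c != "probe_id"]
    for col in sample_cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            probe = df.loc[numeric.isna().idxmax(), "probe_id"]
            raise ValueError(
                f"missing or non-numeric value at probe {probe!r}, "
                f"sample {col!r} in {path}"
            )
        df[col] = numeric
    if layout is not None:
        known = {p.id for p in layout}
        unknown = [p for p in df["probe_id"] if p not in known]
        if unknown:
            raise ValueError(
                f"probe {unknown[0]!r} in intensity table absent from layout"
            )
    return IntensityMatrix.from_frame(df)


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

_REGION_COLS = [
    "id",
    "strand",
    "start",
    "end",
    "length",
    "log2_fold_change",
    "p_score",
    "mean_reference",
    "mean_treated",
    "present_reference",
    "present_treated",
    "n_probes",
    "call",
]


def write_regions(
    regions: Sequence[Region],
    path: str | Path,
    dialect: str = "tsv",
    seqid: str = DEFAULT_SEQID,
) -> None:
    """Write detected regions as a TSV report or a BED6 track.

    The TSV leads with the report columns id, strand, start, end, length,
    log2 fold change and P, then carries the remaining region fields so that
    ``read_regions(write_regions(x)) == x``.  BED6 keeps id, coordinates and
    strand only (score column: P scaled to 0-1000).
    """
    if dialect == "tsv":
        df = pd.DataFrame(
            [
                (
                    r.id,
                    r.strand,
                    r.start,
                    r.end,
                    r.length,
                    r.log2_fold_change,
                    r.p_score,
                    r.mean_reference,
                    r.mean_treated,
                    r.present_reference,
                    r.present_treated,
                    r.n_probes,
                    r.call if r.call is not None else ".",
                )
                for r in regions
            ],
            columns=_REGION_COLS,
        )
        for col in ("log2_fold_change", "p_score", "mean_reference", "mean_treated"):
            # shortest round-trip float representation: lossless read-back
            df[col] = df[col].map(repr)
        df.to_csv(path, sep="\t", index=False)
    elif dialect == "bed6":
        with open(path, "w") as fh:
            for r in regions:
                score = int(round(1000 * min(max(r.p_score, 0.0), 1.0)))
                fh.write(
                    f"{seqid}\t{r.start - 1}\t{r.end}\t{r.id}\t{score}\t{r.strand}\n"
                )
    else:
        raise ValueError(f"unknown region dialect {dialect!r}")


def read_regions(path: str | Path, dialect: str = "tsv") -> list[Region]:
    if dialect == "tsv":
        df = pd.read_csv(
            path, sep="\t", dtype={"id": str, "call": str}, float_precision="round_trip"
        )
        regions = []
        for row in df.itertuples():
            regions.append(
                Region(
                    id=row.id,
                    strand=row.strand,
                    start=int(row.start),
                    end=int(row.end),
                    mean_reference=float(row.mean_reference),
                    mean_treated=float(row.mean_treated),
                    p_score=float(row.p_score),
                    log2_fold_change=float(row.log2_fold_change),
                    present_reference=bool(row.present_reference),
                    present_treated=bool(row.present_treated),
                    n_probes=int(row.n_probes),
                    call=None if row.call == "." else row.call,
                )
            )
        return regions
    if dialect == "bed6":
        regions = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                _, bed_start, bed_end, name, score, strand = line.split("\t")[:6]
                regions.append(
                    Region(
                        id=name,
                        strand=strand.strip(),
                        start=int(bed_start) + 1,
                        end=int(bed_end),
                        mean_reference=float("nan"),
                        mean_treated=float("nan"),
                        p_score=int(score) / 1000.0,
                        log2_fold_change=float("nan"),
                        present_reference=False,
                        present_treated=False,
                        n_probes=0,
                    )
                )
        return regions
    raise ValueError(f"unknown region dialect {dialect!r}")
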