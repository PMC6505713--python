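"""Core containers shared across the pipeline.

All genomic coordinates are 1-based inclusive on a single replicon; BED's
0-based half-open convention is converted at the I/O boundary only
(:mod:`tilescope.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: The two experimental conditions, in canonical column order.
CONDITIONS = ("reference", "treated")

#: Feature kinds accepted in annotations.
GENE_KINDS = ("protein_coding", "ncRNA", "tRNA", "rRNA")


@dataclass(frozen=True)
class GeneFeature:
    """An annotated transcript (gene or structural RNA) on the replicon."""

    id: str
    name: str
    start: int
    end: int
    strand: str
    kind: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(
                f"invalid coordinates for {self.id}: [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r} for {self.id}")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r} for {self.id}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Probe:
    """A single tiling probe with genomic placement."""

    id: str
    start: int
    end: int
    strand: str
    kind: str = "intergenic"  # genic | intergenic

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid probe coordinates [{self.start}, {self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        """Genomic midpoint; membership in a transcript is decided here."""
        return (self.start + self.end) / 2.0


@dataclass
class Region:
    """A detected transcribed segment scored for differential expression.

    ``p_score`` is the probability of differential expression, defined as one
    minus the two-sided Welch t-test p-value over the segment's pooled
    probe x replicate intensities.  ``log2_fold_change`` is
    mean(treated) - mean(reference) on the log2 scale.
    """

    id: str
    strand: str
    start: int
    end: int
    mean_reference: float
    mean_treated: float
    p_score: float
    log2_fold_change: float
    present_reference: bool
    present_treated: bool
    n_probes: int
    call: str | None = None  # differential | similar_expressed | not_expressed

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


class IntensityMatrix:
    """Probes x samples matrix of log2 intensities with sample metadata.

    Samples are named ``<condition>_rep<i>`` with condition in
    :data:`CONDITIONS`.  Values must be finite and probe ids unique.
    """

    def __init__(
        self,
        probe_ids: Sequence[str],
        values: np.ndarray,
        conditions: Sequence[str],
        replicates: Sequence[int],
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D probes x samples array")
        if len(probe_ids) != values.shape[0]:
            raise ValueError("probe id count does not match matrix rows")
        if len(conditions) != values.shape[1] or len(replicates) != values.shape[1]:
            raise ValueError("sample metadata does not match matrix columns")
        if len(set(probe_ids)) != len(probe_ids):
            raise ValueError("probe ids must be unique")
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite intensity at probe {probe_ids[bad[0]]!r}, "
                f"sample column {bad[1]}"
            )
        for c in conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
        self.probe_ids = list(probe_ids)
        self.values = values
        self.conditions = np.asarray(conditions, dtype=object)
        self.replicates = np.asarray(replicates, dtype=int)
        self._row_of = {p: i for i, p in enumerate(self.probe_ids)}

    # -- shape ---------------------------------------------------------------

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def sample_names(self) -> list[str]:
        return [
            f"{c}_rep{r}" for c, r in zip(self.conditions, self.replicates)
        ]

    def n_replicates(self, condition: str) -> int:
        return int(np.sum(self.conditions == condition))

    # -- access --------------------------------------------------------------

    def columns(self, condition: str) -> np.ndarray:
        """Column indices for one condition."""
        return np.flatnonzero(self.conditions == condition)

    def rows(self, probe_ids: Iterable[str]) -> np.ndarray:
        try:
            return np.array([self._row_of[p] for p in probe_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"probe {exc.args[0]!r} not in matrix") from None

    def pooled(self, row_indices: Sequence[int], condition: str) -> np.ndarray:
        """All probe x replicate values for the given rows and condition, flat."""
        rows = np.asarray(row_indices, dtype=int)
        return self.values[np.ix_(rows, self.columns(condition))].ravel()

    def condition_mean(self, row_indices: Sequence[int], condition: str) -> float:
        return float(np.mean(self.pooled(row_indices, condition)))

    # -- conversion ----------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_names)
        df.insert(0, "probe_id", self.probe_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IntensityMatrix":
        """Build from a frame with a ``probe_id`` column and sample columns."""
        import re

        if "probe_id" not in df.columns:
            raise ValueError("intensity table must have a 'probe_id' column")
        sample_cols = [c for c in df.columns if c != "probe_id"]
        conditions, replicates = [], []
        for c in sample_cols:
            m = re.fullmatch(r"([A-Za-z]+)_rep(\d+)", c)
            if not m or m.group(1) not in CONDITIONS:
                raise ValueError(f"cannot parse sample column name {c!r}")
            conditions.append(m.group(1))
            replicates.append(int(m.group(2)))
        return cls(
            probe_ids=list(df["probe_id"]),
            values=df[sample_cols].to_numpy(dtype=float),
            conditions=conditions,
            replicates=replicates,
        )
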