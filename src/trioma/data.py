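"""Core domain containers for the tri-omic expression pipeline.

Every container is a thin, validated wrapper around a :class:`pandas.DataFrame`
or plain dataclass fields.  Genomic coordinates are 0-based half-open
throughout the package; conversion from 1-based formats happens only at the
I/O boundary (:mod:`trioma.io`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Channel",
    "Condition",
    "ExpressionMatrix",
    "SLRMatrix",
    "SampleDesign",
    "ProbeAnnotation",
    "GeneModel",
    "LncLocus",
    "TargetTable",
    "GeneSetCollection",
    "QpcrRecord",
    "UNDETERMINED",
]


class Channel(str, enum.Enum):
    """Which of the three array channels a matrix belongs to."""

    MRNA = "mRNA"
    LNCRNA = "lncRNA"
    MIRNA = "miRNA"


class Condition(str, enum.Enum):
    """Experimental arm: neuronal maturation (days) or OGD injury (hours)."""

    MATURATION = "maturation"
    OGD = "OGD"


#: Sentinel for a qPCR reaction that never crossed threshold within the run.
UNDETERMINED = "Undetermined"


@dataclass
class ExpressionMatrix:
    """Probe x sample matrix of linear-scale, non-negative intensities."""

    channel: Channel
    data: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        self.channel = Channel(self.channel)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe id(s): {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if values.size and (values < 0).any():
            raise ValueError("raw intensities must be non-negative")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.channel == other.channel and self.data.equals(other.data)


@dataclass
class SampleDesign:
    """Maps samples to timepoints and names the baseline reference sample.

    Maturation samples live on a day axis (baseline Day 2); OGD samples on an
    hour axis (baseline 0 hr).
    """

    condition: Condition
    timepoints: dict[str, float]  # sample id -> day or hour
    baseline: str

    def __post_init__(self) -> None:
        self.condition = Condition(self.condition)
        if self.baseline not in self.timepoints:
            raise ValueError(f"baseline sample {self.baseline!r} not in design")
        times = list(self.timepoints.values())
        if sorted(times) != times or len(set(times)) != len(times):
            raise ValueError("timepoints must be strictly increasing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.timepoints)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(list(self.timepoints.values()), dtype=float)


@dataclass
class SLRMatrix:
    """Probe x timepoint Signal Log Ratios relative to a baseline sample.

    ``SLR[p, t] = log2(intensity[p, t] / intensity[p, baseline])`` so the
    baseline column is identically zero.
    """

    data: pd.DataFrame  # index = probe ids, columns = sample ids
    design: SampleDesign

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.design.sample_ids:
            raise ValueError("SLR columns must match the design's samples")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValueError("SLR values must be finite")
        base = self.data[self.design.baseline].to_numpy(dtype=float)
        if base.size and not np.allclose(base, 0.0):
            raise ValueError("baseline column of an SLR matrix must be 0")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> np.ndarray:
        return self.design.times


@dataclass(frozen=True)
class ProbeAnnotation:
    """Vendor association of one array probe with a transcript and gene."""

    probe_id: str
    transcript: str  # NM_/AK/uc/ENSMUST accession
    gene: str  # symbol; empty for intergenic lncRNA probes
    channel: Channel


@dataclass(frozen=True)
class GeneModel:
    """A coding gene: transcript span, exons and optional 3'UTR on one strand.

    Coordinates are 0-based half-open.  The TSS is the transcript start on the
    + strand and ``end - 1`` on the - strand.
    """

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    utr3: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.end <= self.start:
            raise ValueError(f"empty transcript interval for {self.gene_id}")
        exons = tuple(sorted(self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon [{s},{e}) outside transcript of {self.gene_id}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, in transcription order."""
        gaps = [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]
        if self.strand == "-":
            gaps = gaps[::-1]
        return tuple(gaps)

    def promoter(self, size: int) -> tuple[int, int]:
        """Strand-aware interval of ``size`` bp immediately upstream of the TSS."""
        if self.strand == "+":
            return (max(0, self.start - size), self.start)
        return (self.end, self.end + size)


@dataclass(frozen=True)
class LncLocus:
    """A lncRNA locus on the genome (0-based half-open interval)."""

    lnc_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ultraconserved: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.lnc_id}")
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.lnc_id}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


class TargetTable:
    """Deduplicated miRNA -> gene target rows with evidence grade.

    When the same (miRNA, gene) pair is both predicted and validated,
    "validated" wins.
    """

    EVIDENCE = ("predicted", "validated")

    def __init__(self, rows: pd.DataFrame | None = None):
        if rows is None:
            rows = pd.DataFrame(columns=["mirna", "gene", "evidence", "source"])
        rows = rows.reset_index(drop=True)
        bad = set(rows["evidence"]) - set(self.EVIDENCE)
        if bad:
            raise ValueError(f"unknown evidence value(s): {sorted(bad)}")
        # stable dedup: validated beats predicted, first source kept
        rows = rows.copy()
        rows["_rank"] = (rows["evidence"] == "validated").astype(int)
        rows = (
            rows.sort_values("_rank", ascending=False, kind="stable")
            .drop_duplicates(subset=["mirna", "gene"], keep="first")
            .drop(columns="_rank")
            .sort_index()
            .reset_index(drop=True)
        )
        self.rows = rows

    def __len__(self) -> int:
        return len(self.rows)

    def genes_of(self, mirna: str) -> set[str]:
        return set(self.rows.loc[self.rows["mirna"] == mirna, "gene"])

    def mirnas_of(self, gene: str) -> set[str]:
        return set(self.rows.loc[self.rows["gene"] == gene, "mirna"])

    @property
    def mirnas(self) -> set[str]:
        return set(self.rows["mirna"])


class GeneSetCollection:
    """Named gene sets over a background universe (GMT semantics)."""

    def __init__(self, sets: dict[str, set[str]], universe: set[str] | None = None):
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        restricted = {name: members & universe for name, members in sets.items()}
        empty = [name for name, members in restricted.items() if not members]
        if empty:
            raise ValueError(f"gene set(s) empty after universe restriction: {empty}")
        self.sets = restricted
        self.universe = set(universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


@dataclass(frozen=True)
class QpcrRecord:
    """Replicate C_T values for one assay in one sample.

    "Undetermined" reactions are carried as the :data:`UNDETERMINED` sentinel,
    never as a number; each consumer states how it treats the sentinel.
    """

    assay: str
    sample: str
    ct: tuple[float | str, ...]
    is_ntc: bool = False

    def __post_init__(self) -> None:
        if not self.ct:
            raise ValueError("at least one C_T replicate required")
        for v in self.ct:
            if v == UNDETERMINED:
                continue
            if not isinstance(v, (int, float)) or not math.isfinite(v) or not 0 < v <= 40:
                raise ValueError(f"C_T value {v!r} outside (0, 40]")

    @property
    def numeric_ct(self) -> tuple[float, ...]:
        return tuple(float(v) for v in self.ct if v != UNDETERMINED)
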