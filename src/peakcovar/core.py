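"""Core containers shared across the package.

Coordinates are 0-based, half-open throughout (BED convention); formats that
use other conventions (GTF) are converted at I/O time and nowhere else.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: Experimental groups used throughout: unseparated controls, brief separation
#: (handling) and prolonged maternal separation.
GROUPS = ("CTRL", "HD", "MS")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """At least one base in common (half-open semantics)."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site collapsed to a unique (gene, position)."""

    gene_id: str
    gene_name: str
    tss: int
    strand: str
    chrom: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError("tss must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("TSS strand must be '+' or '-'")


_PEAK_COLUMNS = ["chrom", "start", "end", "strand", "score", "q_value"]


@dataclass
class PeakSet:
    """Peaks at one resolution (broad domains or nucleosome-sized subpeaks).

    ``df`` is indexed by peak_id with columns chrom/start/end/strand/score/q_value.
    Annotation layers (gene assignments, bidirectional-promoter flags, genomic
    context) are filled in by :mod:`peakcovar.genomic_io` operations.
    """

    df: pd.DataFrame
    resolution: str = "broad"
    subpeak_parent: dict[str, str] | None = None
    gene_assignments: dict[str, list[str]] = field(default_factory=dict)
    nearest_gene: dict[str, str] = field(default_factory=dict)
    bidirectional: dict[str, bool] = field(default_factory=dict)
    context: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.df
        for col in ("chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"PeakSet frame missing column {col!r}")
        if "strand" not in df.columns:
            df = df.assign(strand=".")
        if "score" not in df.columns:
            df = df.assign(score=0.0)
        if "q_value" not in df.columns:
            df = df.assign(q_value=np.nan)
        df = df[_PEAK_COLUMNS].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any():
            raise ValueError("negative start coordinate")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"peak {bad!r}: start >= end")
        q = df["q_value"].to_numpy(dtype=float)
        ok = np.isnan(q) | ((q >= 0.0) & (q <= 1.0))
        if not ok.all():
            raise ValueError("q_value outside [0, 1]")
        if df.index.has_duplicates:
            raise ValueError("duplicate peak_id")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return list(self.df.index)

    def interval(self, peak_id: str) -> GenomicInterval:
        row = self.df.loc[peak_id]
        return GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]), row["strand"])

    def midpoints(self) -> pd.Series:
        return (self.df["start"] + self.df["end"]) // 2

    def subset(self, ids) -> "PeakSet":
        ids = list(ids)
        keep = set(ids)
        return PeakSet(
            self.df.loc[ids].copy(),
            resolution=self.resolution,
            subpeak_parent=(
                {k: v for k, v in self.subpeak_parent.items() if k in keep}
                if self.subpeak_parent is not None
                else None
            ),
            gene_assignments={k: v for k, v in self.gene_assignments.items() if k in keep},
            nearest_gene={k: v for k, v in self.nearest_gene.items() if k in keep},
            bidirectional={k: v for k, v in self.bidirectional.items() if k in keep},
            context={k: v for k, v in self.context.items() if k in keep},
        )


def validate_subpeaks(subpeaks: PeakSet, broad: PeakSet) -> None:
    """Check every subpeak lies within its parent broad peak."""
    if subpeaks.subpeak_parent is None:
        raise ValueError("subpeak PeakSet has no parent map")
    for sid in subpeaks.ids:
        pid = subpeaks.subpeak_parent.get(sid)
        if pid is None:
            raise ValueError(f"subpeak {sid!r} has no parent")
        s = subpeaks.df.loc[sid]
        p = broad.df.loc[pid]
        if not (p["chrom"] == s["chrom"] and p["start"] <= s["start"] and s["end"] <= p["end"]):
            raise ValueError(f"subpeak {sid!r} not contained in parent {pid!r}")


@dataclass
class SampleMeta:
    """Sample sheet: one row per sample with group, litter and optional paths.

    ``df`` is indexed by sample_id with at least a ``group`` column; ``litter``,
    ``file`` and ``library_total`` are optional.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.df.columns:
            raise ValueError("sample sheet needs a 'group' column")
        unknown = set(self.df["group"]) - set(GROUPS) - {"INPUT"}
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate sample_id")
        if "library_total" in self.df.columns:
            lt = self.df["library_total"].dropna()
            if (lt <= 0).any():
                raise ValueError("library_total must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def group_of(self, sample_id: str) -> str:
        return self.df.loc[sample_id, "group"]

    def samples_in(self, group: str) -> list[str]:
        return list(self.df.index[self.df["group"] == group])

    @classmethod
    def from_tsv(cls, path) -> "SampleMeta":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if "sample_id" not in df.columns:
            raise ValueError("sample sheet needs a 'sample_id' column")
        return cls(df.set_index("sample_id"))

    def to_tsv(self, path) -> None:
        self.df.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentMatrix:
    """Region-by-sample matrix of counts or log2 normalized enrichment."""

    values: pd.DataFrame
    resolution: str = "broad"
    normalized: bool = False
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate region_ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample_ids")
        arr = self.values.to_numpy()
        if not self.normalized:
            if (arr < 0).any():
                raise ValueError("raw counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("raw counts must be integers")
        if self.size_factors is not None:
            sf = self.size_factors.reindex(self.values.columns)
            if sf.isna().any() or (sf <= 0).any():
                raise ValueError("size_factors must be positive and cover all samples")
            self.size_factors = sf

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def normalized_linear(self) -> pd.DataFrame:
        """Counts divided by size factors (linear scale)."""
        if self.normalized:
            raise ValueError("matrix already normalized")
        if self.size_factors is None:
            raise ValueError("size factors not set")
        return self.values / self.size_factors

    def to_tsv(self, path) -> None:
        self.values.rename_axis("region_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, resolution: str = "broad", normalized: bool = False) -> "EnrichmentMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, resolution=resolution, normalized=normalized)
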