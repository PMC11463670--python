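"""Core in-memory containers shared across the pipeline.

Counts are held as sparse features x cells matrices; genomic coordinates are
0-based half-open everywhere (BED-native). Peak and gene tables are pandas
DataFrames with fixed column contracts so every stage can read every other
stage's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """Malformed on-disk input (bad dimensions, unparseable rows)."""


class ValidationError(ValueError):
    """Well-formed input that violates a domain invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("empty chromosome name")
        if self.start >= self.end:
            raise ValidationError(
                f"interval start {self.start} >= end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced ATAC fragment with its cell barcode and duplicate count."""

    interval: GenomicInterval
    barcode: str
    duplicate_count: int = 1

    def __post_init__(self) -> None:
        if self.duplicate_count < 1:
            raise ValidationError("duplicate_count must be >= 1")


@dataclass
class CountMatrix:
    """Sparse non-negative integer counts, features x cells.

    Used for both RNA (genes x cells) and ATAC (peaks x cells). Feature and
    cell identifier lists are ordered and unique; ``values`` is CSR.
    """

    values: sp.csr_matrix
    feature_ids: list[str]
    cell_ids: list[str]
    modality: str = "rna"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.feature_ids = list(self.feature_ids)
        self.cell_ids = list(self.cell_ids)
        if self.modality not in ("rna", "atac"):
            raise ValidationError(f"unknown modality {self.modality!r}")
        nf, nc = self.values.shape
        if nf != len(self.feature_ids) or nc != len(self.cell_ids):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.cell_ids)} cells"
            )
        if len(set(self.feature_ids)) != nf:
            raise ValidationError("duplicate feature identifiers")
        if len(set(self.cell_ids)) != nc:
            raise ValidationError("duplicate cell identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("negative count entry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_ids)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cell_ids)}

    def subset_cells(self, cells: Sequence[str]) -> "CountMatrix":
        idx = self.cell_index()
        cols = [idx[c] for c in cells]
        return CountMatrix(
            self.values[:, cols], self.feature_ids, list(cells), self.modality
        )

    def subset_features(self, features: Sequence[str]) -> "CountMatrix":
        idx = self.feature_index()
        rows = [idx[f] for f in features]
        return CountMatrix(
            self.values[rows, :], list(features), self.cell_ids, self.modality
        )


@dataclass
class PeakSet:
    """ATAC peaks with per-peak GC fraction and mean accessibility.

    ``gc_content`` and ``mean_accessibility`` align 1:1 with ``intervals``;
    GC is a fraction in [0, 1] supplied by the caller (from sequence or a
    reference table), never computed from a genome here.
    """

    intervals: list[GenomicInterval]
    gc_content: np.ndarray = None
    mean_accessibility: np.ndarray = None
    ids: list[str] = None

    def __post_init__(self) -> None:
        n = len(self.intervals)
        if self.gc_content is None:
            self.gc_content = np.full(n, np.nan)
        self.gc_content = np.asarray(self.gc_content, dtype=float)
        if self.mean_accessibility is None:
            self.mean_accessibility = np.zeros(n)
        self.mean_accessibility = np.asarray(self.mean_accessibility, dtype=float)
        if self.ids is None:
            self.ids = [
                f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.intervals
            ]
        if len(self.gc_content) != n or len(self.mean_accessibility) != n:
            raise ValidationError("per-peak annotation length mismatch")
        if len(self.ids) != n:
            raise ValidationError("peak id list length mismatch")
        finite = self.gc_content[np.isfinite(self.gc_content)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("gc_content outside [0, 1]")
        if self.mean_accessibility.size and self.mean_accessibility.min() < 0:
            raise ValidationError("negative mean accessibility")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def subset(self, index: Sequence[int]) -> "PeakSet":
        index = list(index)
        return PeakSet(
            [self.intervals[i] for i in index],
            self.gc_content[index],
            self.mean_accessibility[index],
            [self.ids[i] for i in index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak": self.ids,
                "chrom": [iv.chrom for iv in self.intervals],
                "start": [iv.start for iv in self.intervals],
                "end": [iv.end for iv in self.intervals],
                "gc": self.gc_content,
                "mean_accessibility": self.mean_accessibility,
            }
        )


GENE_TABLE_COLUMNS = [
    "gene",
    "chrom",
    "start",
    "end",
    "strand",
    "tss",
    "is_mitochondrial",
    "is_chrY",
]


def make_gene_table(
    genes: Sequence[str],
    chroms: Sequence[str],
    starts: Sequence[int],
    ends: Sequence[int],
    strands: Sequence[str],
    mito_chrom: str = "chrM",
    y_chrom: str = "chrY",
) -> pd.DataFrame:
    """Assemble the gene-model table; TSS is strand-aware (start if '+',
    end-1 if '-'), and mitochondrial / Y-linked flags follow the chromosome
    name so filters downstream never re-derive them."""
    df = pd.DataFrame(
        {
            "gene": list(genes),
            "chrom": list(chroms),
            "start": np.asarray(starts, dtype=int),
            "end": np.asarray(ends, dtype=int),
            "strand": list(strands),
        }
    )
    if (df["start"] >= df["end"]).any():
        raise ValidationError("gene with start >= end")
    if df["gene"].duplicated().any():
        raise ValidationError("duplicate gene identifiers")
    df["tss"] = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    df["is_mitochondrial"] = df["chrom"] == mito_chrom
    df["is_chrY"] = df["chrom"] == y_chrom
    return df[GENE_TABLE_COLUMNS]
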