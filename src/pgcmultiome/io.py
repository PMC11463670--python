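"""Readers and writers for the on-disk formats the pipeline exchanges.

Count matrices travel as MatrixMarket triplets plus feature/barcode TSVs
(the plain-text layout of 10x-style output); peaks as BED3+1 with GC in the
fourth column; fragments as the 5-column TSV dialect (chrom, start, end,
barcode, duplicate count), optionally gzipped; motifs as JASPAR text.
All coordinates are 0-based half-open on disk and in memory.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import (
    CountMatrix,
    FormatError,
    FragmentRecord,
    GenomicInterval,
    PeakSet,
    ValidationError,
)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    modality: str = "rna",
) -> CountMatrix:
    """Read a MatrixMarket coordinate matrix with its feature/barcode lists."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}")
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    mat = sp.csr_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix is {mat.shape[0]}x{mat.shape[1]} but found "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    if mat.nnz and mat.data.min() < 0:
        raise ValidationError("negative entry in count matrix")
    mat.data = np.rint(mat.data).astype(np.int64)
    mat.eliminate_zeros()
    return CountMatrix(mat, features, barcodes, modality)


def write_count_matrix(cm: CountMatrix, directory: str | Path, prefix: str = "") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = cm.values.tocoo()
    # canonical triplet order so identical matrices serialize identically
    order = np.lexsort((coo.row, coo.col))
    canonical = sp.coo_matrix(
        (coo.data[order], (coo.row[order], coo.col[order])), shape=coo.shape
    )
    scipy.io.mmwrite(str(directory / f"{prefix}matrix.mtx"), canonical, field="integer")
    (directory / f"{prefix}features.tsv").write_text(
        "".join(f"{f}\n" for f in cm.feature_ids)
    )
    (directory / f"{prefix}barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in cm.cell_ids)
    )


def _read_id_column(path: str | Path) -> list[str]:
    with _open_maybe_gzip(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


# ---------------------------------------------------------------------------
# peaks (BED3+)


def read_peaks_bed(path: str | Path) -> PeakSet:
    """Read peaks from BED; optional 4th column is GC fraction, 5th mean
    accessibility."""
    intervals, gc, acc = [], [], []
    with _open_maybe_gzip(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer coordinates")
            intervals.append(GenomicInterval(parts[0], start, end))
            gc.append(float(parts[3]) if len(parts) > 3 else np.nan)
            acc.append(float(parts[4]) if len(parts) > 4 else 0.0)
    return PeakSet(intervals, np.array(gc), np.array(acc))


def write_peaks_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv, g, a in zip(peaks.intervals, peaks.gc_content, peaks.mean_accessibility):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g:.6g}\t{a:.6g}\n")


# ---------------------------------------------------------------------------
# JASPAR PFMs


def read_jaspar_pfm(path: str | Path) -> list[dict]:
    """Parse JASPAR-style text motifs.

    Each motif is ``>ID NAME`` followed by four rows of counts in base order
    A, C, G, T (bare numbers, or the bracketed ``A [ 1 2 3 ]`` dialect).
    Returns dicts with ``id``, ``name`` and a 4xL float ``pfm``.
    """
    motifs: list[dict] = []
    header: str | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise FormatError(f"motif {header!r}: expected 4 base rows, got {len(rows)}")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise FormatError(f"motif {header!r}: rows of unequal length")
        pfm = np.array(rows, dtype=float)
        if pfm.min() < 0:
            raise ValidationError(f"motif {header!r}: negative count")
        parts = header.split(None, 1)
        motifs.append(
            {
                "id": parts[0],
                "name": parts[1] if len(parts) > 1 else parts[0],
                "pfm": pfm,
            }
        )
        header, rows = None, []

    with _open_maybe_gzip(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                continue
            if header is None:
                raise FormatError(f"{path}:{ln}: counts before any '>' header")
            clean = line.replace("[", " ").replace("]", " ")
            toks = clean.split()
            if toks and toks[0].upper() in "ACGT" and len(toks[0]) == 1:
                toks = toks[1:]
            try:
                rows.append([float(t) for t in toks])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-numeric count")
    flush()
    return motifs


def write_jaspar_pfm(motifs: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m['id']} {m['name']}\n")
            for row in np.asarray(m["pfm"]):
                fh.write(" ".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# fragments


def read_fragments(path: str | Path) -> Iterator[FragmentRecord]:
    """Stream 5-column fragment records in file order."""
    with _open_maybe_gzip(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{ln}: fewer than 5 fragment columns")
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[4])
            except ValueError:
                raise FormatError(f"{path}:{ln}: non-integer field")
            yield FragmentRecord(
                GenomicInterval(parts[0], start, end), parts[3], count
            )


def read_fragments_frame(path: str | Path) -> pd.DataFrame:
    """Vectorized fragment reader for whole-file analyses."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "barcode", "count"],
        dtype={"chrom": str, "barcode": str},
    )
    if len(df) == 0:
        return df
    try:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["count"] = df["count"].astype(np.int64)
    except (ValueError, TypeError):
        raise FormatError(f"{path}: non-integer fragment field")
    if (df["start"] >= df["end"]).any():
        raise ValidationError(f"{path}: fragment with start >= end")
    return df


def write_fragments(df: pd.DataFrame, path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# FASTA (peak sequences)


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# gene tables / generic TSV


def read_gene_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "start", "end", "strand", "tss"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing gene-table columns {sorted(missing)}")
    for flag in ("is_mitochondrial", "is_chrY"):
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a stage output table deterministically (fixed float format)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _open_maybe_gzip(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")
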