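"""Per-cell QC metrics, threshold filtering, peak filtering and the
marker-count cell-type triage.

All QC inequalities are strict: a cell sitting exactly on a bound is
excluded, matching the convention the thresholds were published with.
The nucleosome signal is the mono-nucleosomal (147-294 bp) to
sub-nucleosomal (<147 bp) fragment-count ratio; TSS enrichment is the
centre-vs-flank per-bp coverage fold over all TSS windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import DEFAULT_MARKERS, PipelineConfig
from .core import CountMatrix, PeakSet, ValidationError

TSS_SENTINEL = 1e6  # reported when flank coverage is 0 but centre is not


def compute_rna_qc(rna: CountMatrix, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-cell RNA totals and mitochondrial percentage.

    ``pct_mito`` is 100 x (counts in mitochondrial genes) / (total counts),
    defined as 0 for an all-zero cell.
    """
    known = set(genes["gene"])
    unknown = [f for f in rna.feature_ids if f not in known]
    if unknown:
        raise ValidationError(f"features missing from gene table: {unknown[:5]}")
    mito = genes.set_index("gene")["is_mitochondrial"].reindex(rna.feature_ids)
    mito_mask = mito.to_numpy(dtype=bool)
    total = np.asarray(rna.values.sum(axis=0)).ravel()
    mito_counts = np.asarray(rna.values[mito_mask, :].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * mito_counts / np.maximum(total, 1e-12), 0.0)
    return pd.DataFrame(
        {"barcode": rna.cell_ids, "n_count_rna": total.astype(int), "pct_mito": pct}
    )


def compute_atac_counts(atac: CountMatrix) -> pd.DataFrame:
    total = np.asarray(atac.values.sum(axis=0)).ravel()
    return pd.DataFrame({"barcode": atac.cell_ids, "n_count_atac": total.astype(int)})


def compute_nucleosome_signal(
    fragments: pd.DataFrame, cell_ids: list[str]
) -> pd.Series:
    """Mono-nucleosomal over sub-nucleosomal fragment-count ratio per cell.

    ratio = #len in [147, 294] / max(1, #len < 147); cells without
    fragments score 0.
    """
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    mono = (lengths >= 147) & (lengths <= 294)
    sub = lengths < 147
    df = pd.DataFrame({"barcode": fragments["barcode"], "mono": mono, "sub": sub})
    agg = df.groupby("barcode", sort=False)[["mono", "sub"]].sum()
    agg = agg.reindex(cell_ids, fill_value=0)
    ratio = agg["mono"] / np.maximum(agg["sub"], 1)
    ratio.name = "nucleosome_signal"
    return ratio.astype(float)


def compute_tss_enrichment(
    fragments: pd.DataFrame,
    genes: pd.DataFrame,
    cell_ids: list[str],
    center_halfwidth: int = 250,
    flank_inner: int = 1900,
    flank_outer: int = 2000,
) -> pd.Series:
    """Per-cell TSS enrichment fold.

    Mean per-bp fragment coverage in TSS +/- ``center_halfwidth`` divided by
    mean per-bp coverage in the two distal flank windows
    [TSS-2000, TSS-1900) and (TSS+1900, TSS+2000], aggregated over every
    TSS. 0/0 gives 0; nonzero centre over zero flank gives the sentinel.
    """
    if len(genes) == 0:
        raise ValidationError("empty gene table")
    cell_code = {c: i for i, c in enumerate(cell_ids)}
    center_bp = np.zeros(len(cell_ids))
    flank_bp = np.zeros(len(cell_ids))
    center_width_total = 0
    flank_width_total = 0

    for chrom, gsub in genes.groupby("chrom"):
        tss = np.sort(gsub["tss"].to_numpy())
        windows_c = np.stack([tss - center_halfwidth, tss + center_halfwidth + 1], axis=1)
        windows_f = np.concatenate(
            [
                np.stack([tss - flank_outer, tss - flank_inner], axis=1),
                np.stack([tss + flank_inner + 1, tss + flank_outer + 1], axis=1),
            ]
        )
        windows_f = windows_f[np.argsort(windows_f[:, 0])]
        center_width_total += windows_c.shape[0] * (2 * center_halfwidth + 1)
        flank_width_total += windows_f.shape[0] * (flank_outer - flank_inner)

        frag = fragments[fragments["chrom"] == chrom]
        if len(frag) == 0:
            continue
        fs = frag["start"].to_numpy()
        fe = frag["end"].to_numpy()
        codes = frag["barcode"].map(cell_code).to_numpy()
        keep = ~pd.isna(codes)
        fs, fe, codes = fs[keep], fe[keep], codes[keep].astype(int)
        for wins, acc in ((windows_c, center_bp), (windows_f, flank_bp)):
            _accumulate_overlap(fs, fe, codes, wins, acc)

    if center_width_total == 0:
        raise ValidationError("no TSS windows")
    center_cov = center_bp / center_width_total
    flank_cov = flank_bp / max(flank_width_total, 1)
    fold = np.zeros(len(cell_ids))
    nz = flank_cov > 0
    fold[nz] = center_cov[nz] / flank_cov[nz]
    fold[(~nz) & (center_cov > 0)] = TSS_SENTINEL
    return pd.Series(fold, index=cell_ids, name="tss_enrichment")


def _accumulate_overlap(
    fs: np.ndarray,
    fe: np.ndarray,
    codes: np.ndarray,
    windows: np.ndarray,
    acc: np.ndarray,
) -> None:
    """Add overlap basepairs of each fragment with sorted disjoint windows
    to acc[cell]. Fragments are short relative to window spacing, so only a
    few candidate windows per fragment need checking."""
    if len(windows) == 0 or len(fs) == 0:
        return
    starts = windows[:, 0]
    lo = np.searchsorted(starts, fs, side="right") - 1
    max_extra = 3
    for off in range(max_extra):
        idx = lo + off
        ok = (idx >= 0) & (idx < len(windows))
        if not ok.any():
            continue
        ws = np.where(ok, windows[np.clip(idx, 0, len(windows) - 1), 0], 0)
        we = np.where(ok, windows[np.clip(idx, 0, len(windows) - 1), 1], 0)
        ov = np.minimum(fe, we) - np.maximum(fs, ws)
        ov = np.where(ok, np.maximum(ov, 0), 0)
        np.add.at(acc, codes, ov)


def compute_qc_metrics(
    rna: CountMatrix,
    atac: CountMatrix,
    fragments: pd.DataFrame,
    genes: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the full per-cell QC table over the shared barcode set."""
    m = compute_rna_qc(rna, genes).set_index("barcode")
    m = m.join(compute_atac_counts(atac).set_index("barcode"))
    m["nucleosome_signal"] = compute_nucleosome_signal(fragments, rna.cell_ids)
    m["tss_enrichment"] = compute_tss_enrichment(fragments, genes, rna.cell_ids)
    return m.reset_index()


def filter_cells(
    metrics: pd.DataFrame, config: PipelineConfig
) -> tuple[list[str], pd.DataFrame]:
    """Apply all strict-inequality per-cell QC rules.

    Returns the retained barcodes and a per-rule exclusion count table
    (cells can fail several rules; counts are per rule, not disjoint).
    """
    m = metrics
    rules = {
        "rna_count_low": m["n_count_rna"] > config.rna_count_min,
        "rna_count_high": m["n_count_rna"] < config.rna_count_max,
        "pct_mito": m["pct_mito"] < config.pct_mito_max,
        "atac_count_low": m["n_count_atac"] > config.atac_count_min,
        "atac_count_high": m["n_count_atac"] < config.atac_count_max,
        "nucleosome_signal": m["nucleosome_signal"] < config.nucleosome_signal_max,
        "tss_enrichment": m["tss_enrichment"] > config.tss_enrichment_min,
    }
    passed = np.ones(len(m), dtype=bool)
    counts = []
    for name, ok in rules.items():
        ok = ok.to_numpy()
        counts.append({"rule": name, "excluded": int((~ok).sum())})
        passed &= ok
    retained = m.loc[passed, "barcode"].tolist()
    return retained, pd.DataFrame(counts)


def filter_peaks(
    peaks: PeakSet,
    standard_chroms: set[str] | list[str],
    blacklist: PeakSet | None = None,
    width_min: int = 20,
    width_max: int = 10000,
) -> tuple[PeakSet, np.ndarray]:
    """Retain peaks with width strictly inside (width_min, width_max), on a
    standard chromosome, and with zero blacklist overlap. Returns the
    retained PeakSet and the boolean keep mask over the input."""
    standard = set(standard_chroms)
    keep = np.ones(len(peaks), dtype=bool)
    for i, iv in enumerate(peaks.intervals):
        if not (width_min < iv.width < width_max):
            keep[i] = False
        elif iv.chrom not in standard:
            keep[i] = False
    if blacklist is not None and len(blacklist):
        bl_by_chrom: dict[str, list] = {}
        for biv in blacklist.intervals:
            bl_by_chrom.setdefault(biv.chrom, []).append(biv)
        for i, iv in enumerate(peaks.intervals):
            if not keep[i]:
                continue
            for biv in bl_by_chrom.get(iv.chrom, ()):
                if iv.start < biv.end and biv.start < iv.end:
                    keep[i] = False
                    break
    return peaks.subset(np.flatnonzero(keep)), keep


def call_cell_types(
    rna: CountMatrix, marker_config: dict | None = None, germ_rule: str = "any"
) -> pd.DataFrame:
    """Count-based cell-type triage on raw integer counts.

    PGC: at least one germ-positive marker detected (>= 1 count; ``germ_rule``
    'all' requires every germ marker) AND every soma-exclusion marker at
    exactly 0. Supporting: Wt1 >= 2 AND every supporting-exclusion marker at
    0. Cells matching both rules are 'excluded' with reason 'ambiguous';
    everything else is 'other'.
    """
    markers = marker_config or DEFAULT_MARKERS
    fi = rna.feature_index()
    for role, names in markers.items():
        for g in names:
            if g not in fi:
                raise ValidationError(f"marker gene {g!r} ({role}) absent from matrix")

    def rows(names: list[str]) -> np.ndarray:
        return rna.values[[fi[g] for g in names], :].toarray()

    germ = rows(markers["germ_positive"])
    soma_excl = rows(markers["soma_exclusion"])
    supp_pos = rows(markers["supporting_positive"])
    supp_excl = rows(markers["supporting_exclusion"])

    if germ_rule == "all":
        germ_ok = (germ >= 1).all(axis=0)
    else:
        germ_ok = (germ >= 1).any(axis=0)
    is_pgc = germ_ok & (soma_excl == 0).all(axis=0)
    is_supp = (supp_pos >= 2).all(axis=0) & (supp_excl == 0).all(axis=0)

    label = np.full(len(rna.cell_ids), "other", dtype=object)
    reason = np.full(len(rna.cell_ids), "no_rule", dtype=object)
    label[is_pgc] = "PGC"
    reason[is_pgc] = "germ_markers"
    label[is_supp] = "supporting"
    reason[is_supp] = "wt1_rule"
    both = is_pgc & is_supp
    label[both] = "excluded"
    reason[both] = "ambiguous"
    return pd.DataFrame({"barcode": rna.cell_ids, "label": label, "reason": reason})


def drop_mito_features(rna: CountMatrix, genes: pd.DataFrame) -> CountMatrix:
    """Remove mitochondrial genes; cell identities are untouched."""
    mito = set(genes.loc[genes["is_mitochondrial"], "gene"])
    keep = [f for f in rna.feature_ids if f not in mito]
    return rna.subset_features(keep)
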