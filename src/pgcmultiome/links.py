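"""Correlation-based peak-to-gene linkage with matched-background z-scores.

For each peak-gene pair within the distance window, the Pearson correlation
of peak accessibility with gene expression across cells is compared with a
null of correlations from background peaks matched to the focal peak on GC
content and mean accessibility (decile x decile binning, widening to
neighboring bins when a stratum is short). The z-score against that null
gives a one-sided upper-tail p; retained links need p < alpha and z > 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from .core import PeakSet, ValidationError


def candidate_pairs(
    peaks: PeakSet,
    genes: pd.DataFrame,
    max_distance: int = 500_000,
) -> pd.DataFrame:
    """All (peak, gene) pairs on the same chromosome with peak midpoint
    within ``max_distance`` of the gene TSS."""
    rows = []
    peak_tbl = pd.DataFrame(
        {
            "peak": peaks.ids,
            "chrom": [iv.chrom for iv in peaks.intervals],
            "mid": [iv.midpoint for iv in peaks.intervals],
            "pidx": np.arange(len(peaks)),
        }
    )
    for chrom, psub in peak_tbl.groupby("chrom"):
        gsub = genes[genes["chrom"] == chrom]
        if len(gsub) == 0:
            continue
        tss = gsub["tss"].to_numpy()
        order = np.argsort(tss)
        tss_sorted = tss[order]
        names = gsub["gene"].to_numpy()[order]
        gidx = gsub.index.to_numpy()[order]
        mids = psub["mid"].to_numpy()
        lo = np.searchsorted(tss_sorted, mids - max_distance, side="left")
        hi = np.searchsorted(tss_sorted, mids + max_distance, side="right")
        for (pk, pidx, mid, l, h) in zip(
            psub["peak"], psub["pidx"], mids, lo, hi
        ):
            for j in range(l, h):
                rows.append(
                    {
                        "peak": pk,
                        "gene": names[j],
                        "peak_index": pidx,
                        "distance": int(abs(mid - tss_sorted[j])),
                    }
                )
    return pd.DataFrame(rows, columns=["peak", "gene", "peak_index", "distance"])


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    ok = sd.ravel() > 0
    sd[sd == 0] = 1.0
    return (X - mu) / sd, ok


def _match_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Decile codes (equal-frequency bins; tied values share a bin)."""
    ranks = pd.Series(values).rank(method="average").to_numpy()
    return np.minimum(((ranks - 1) * n_bins / len(values)).astype(int), n_bins - 1)


def sample_matched_background(
    focal: int,
    gc_bins: np.ndarray,
    acc_bins: np.ndarray,
    n: int,
    rng: np.random.Generator,
    exclude: set[int] | None = None,
) -> np.ndarray:
    """Background peaks from the focal peak's (GC decile, accessibility
    decile) stratum, widening ring by ring in bin space when short."""
    exclude = exclude or {focal}
    gb, ab = gc_bins[focal], acc_bins[focal]
    chosen: list[int] = []
    for radius in range(0, 10):
        ok = (np.abs(gc_bins - gb) <= radius) & (np.abs(acc_bins - ab) <= radius)
        pool = np.flatnonzero(ok)
        pool = pool[~np.isin(pool, list(exclude) + chosen)]
        need = n - len(chosen)
        if len(pool) >= need:
            chosen.extend(rng.choice(pool, size=need, replace=False).tolist())
            break
        chosen.extend(pool.tolist())
    return np.array(chosen[:n], dtype=int)


def link_peaks(
    atac_normalized: sp.spmatrix | np.ndarray,
    rna_normalized: sp.spmatrix | np.ndarray,
    peak_ids: list[str],
    gene_ids: list[str],
    pairs: pd.DataFrame,
    peaks: PeakSet,
    n_background: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Score candidate peak-gene pairs against GC/accessibility-matched
    background peaks.

    Returns one row per scoreable pair with pearson_r, bg_mean, bg_sd,
    z_score, one-sided p and the retained flag (p < alpha and z > 0).
    Zero-variance peaks or genes are skipped with a reason.
    """
    A = atac_normalized.toarray() if sp.issparse(atac_normalized) else np.asarray(atac_normalized, dtype=float)
    R = rna_normalized.toarray() if sp.issparse(rna_normalized) else np.asarray(rna_normalized, dtype=float)
    if A.shape[1] != R.shape[1]:
        raise ValidationError("matrices cover different cell sets")
    if n_background > A.shape[0] - 1:
        raise ValidationError("n_background exceeds available peaks")
    n_cells = A.shape[1]
    rng = np.random.default_rng(seed)

    Za, ok_a = _standardize_rows(A)
    Zr, ok_r = _standardize_rows(R)
    pi = {p: i for i, p in enumerate(peak_ids)}
    gi = {g: i for i, g in enumerate(gene_ids)}

    gc = np.nan_to_num(peaks.gc_content, nan=float(np.nanmean(peaks.gc_content)) if np.isfinite(peaks.gc_content).any() else 0.5)
    gc_bins = _match_bins(gc)
    acc_bins = _match_bins(peaks.mean_accessibility)

    # gene universe actually referenced by the pairs
    genes_used = sorted({g for g in pairs["gene"] if g in gi})
    col_of = {g: j for j, g in enumerate(genes_used)}
    gidx = np.array([gi[g] for g in genes_used], dtype=int)
    # full peak x gene correlation matrix in one BLAS product; background
    # nulls are then simple lookups
    C = (Za @ Zr[gidx].T) / n_cells

    rows = []
    for p_name, grp in pairs.groupby("peak", sort=False):
        p_idx = pi[p_name]
        cols, dists, names = [], [], []
        for _, pr in grp.iterrows():
            g = pr["gene"]
            if g not in col_of:
                continue
            if not ok_a[p_idx] or not ok_r[gi[g]]:
                rows.append(
                    {
                        "peak": p_name, "gene": g,
                        "distance": pr.get("distance", np.nan),
                        "pearson_r": np.nan, "bg_mean": np.nan, "bg_sd": np.nan,
                        "z_score": np.nan, "p_value": np.nan,
                        "retained": False, "reason": "zero_variance",
                    }
                )
                continue
            cols.append(col_of[g])
            dists.append(pr.get("distance", np.nan))
            names.append(g)
        if not cols:
            continue
        bg = sample_matched_background(p_idx, gc_bins, acc_bins, n_background, rng)
        cols_arr = np.array(cols, dtype=int)
        r = C[p_idx, cols_arr]
        null_r = C[np.ix_(bg, cols_arr)]
        bg_mean = null_r.mean(axis=0)
        bg_sd = null_r.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(bg_sd > 0, (r - bg_mean) / np.maximum(bg_sd, 1e-300), 0.0)
        p = norm.sf(z)
        for g, d, rr, bm, bs, zz, pp in zip(names, dists, r, bg_mean, bg_sd, z, p):
            rows.append(
                {
                    "peak": p_name, "gene": g, "distance": d,
                    "pearson_r": float(rr), "bg_mean": float(bm),
                    "bg_sd": float(bs), "z_score": float(zz),
                    "p_value": float(pp),
                    "retained": bool(pp < alpha and zz > 0), "reason": "",
                }
            )
    return pd.DataFrame(rows)


def links_for_genes(links: pd.DataFrame, gene_list: list[str]) -> pd.DataFrame:
    """Links whose gene is in the list, ordered by (gene, p)."""
    keep = links[links["gene"].isin(set(gene_list))]
    return keep.sort_values(["gene", "p_value"], kind="mergesort").reset_index(drop=True)


def dap_deg_overlap(
    daps: list[str], degs: list[str], links: pd.DataFrame
) -> float:
    """Fraction of linked DEGs having at least one differentially
    accessible linked peak. NaN when no DEG has a link."""
    dap_set = set(daps)
    linked = links[links["retained"]] if "retained" in links.columns else links
    by_gene = linked.groupby("gene")["peak"].agg(set)
    deg_linked = [g for g in degs if g in by_gene.index]
    if not deg_linked:
        return float("nan")
    num = sum(1 for g in deg_linked if by_gene[g] & dap_set)
    return num / len(deg_linked)
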