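"""Wilcoxon rank-sum differential testing, marker discovery, BH correction,
peak annotation and gene-set over-representation.

The rank-sum test switches between an exact null (full enumeration of the
U distribution over rank assignments, which handles ties correctly) for
small groups and the tie-corrected, continuity-corrected normal
approximation otherwise. Log2 fold changes use a pseudocount of 1 on
de-logged normalized means. ``pct`` is the fraction of cells with a
nonzero count.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom, norm, rankdata
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix, PeakSet, ValidationError

EXACT_ENUMERATION_CAP = 200_000  # max C(n1+n2, min) for the exact path


def wilcoxon_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p-value.

    Exact enumeration of the U distribution (ties handled by enumerating
    rank assignments) when the smaller group has <= 8 observations and the
    enumeration is tractable; otherwise the normal approximation with tie
    and continuity corrections. Pooled all-identical values give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    ranks = rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2

    if min(n1, n2) <= 8 and comb(n1 + n2, min(n1, n2)) <= EXACT_ENUMERATION_CAP:
        return _exact_u_p(ranks, n1, u1)
    return _normal_u_p(ranks, n1, n2, u1)


def _exact_u_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    n = len(ranks)
    k = min(n1, n - n1)
    swap = k != n1
    total = comb(n, k)
    base = k * (k + 1) / 2
    count = 0
    for combo in combinations(range(n), k):
        u = ranks[list(combo)].sum() - base
        if swap:
            u = n1 * (n - n1) - u
        # two-sided: as or more extreme on either side of the mean
        if abs(u - n1 * (n - n1) / 2) >= abs(u_obs - n1 * (n - n1) / 2) - 1e-9:
            count += 1
    return count / total


def _normal_u_p(ranks: np.ndarray, n1: int, n2: int, u1: float) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    return float(min(1.0, 2 * norm.sf(max(z, 0.0))))


def _vectorized_wilcoxon(
    X: np.ndarray, mask1: np.ndarray, mask2: np.ndarray
) -> np.ndarray:
    """Normal-approximation rank-sum p per row of X (features x cells)."""
    sub = X[:, np.concatenate([np.flatnonzero(mask1), np.flatnonzero(mask2)])]
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    n = n1 + n2
    ranks = rankdata(sub, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    srt = np.sort(sub, axis=1)
    tie_term = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        # run lengths of tied values
        _, counts = np.unique(srt[i], return_counts=True)
        tie_term[i] = (counts.astype(float) ** 3 - counts).sum()
    var = n1 * n2 / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    flat = np.ptp(sub, axis=1) == 0
    z = np.zeros(X.shape[0])
    ok = var > 0
    z[ok] = (np.abs(u1[ok] - mu) - 0.5) / np.sqrt(var[ok])
    p = np.minimum(1.0, 2 * norm.sf(np.maximum(z, 0.0)))
    p[flat] = 1.0
    return p


def log2_fold_change(mean1: np.ndarray, mean2: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    mean1 = np.asarray(mean1, dtype=float)
    mean2 = np.asarray(mean2, dtype=float)
    if (mean1 < 0).any() or (mean2 < 0).any():
        raise ValidationError("means must be non-negative")
    return np.log2((mean1 + pseudocount) / (mean2 + pseudocount))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def find_markers(
    counts: sp.spmatrix | np.ndarray,
    normalized: sp.spmatrix | np.ndarray,
    feature_ids: list[str],
    cells_group1: np.ndarray,
    cells_group2: np.ndarray,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
    p_adjust: str = "bonferroni_all",
) -> pd.DataFrame:
    """Differential features between two cell groups.

    Features are pre-filtered to max(pct1, pct2) >= min_pct and
    |log2fc| >= logfc_threshold; the rank-sum test runs on normalized
    values. ``p_adjust`` is either "bonferroni_all" (adjust over every
    feature in the matrix, the convention of the marker-finding tools this
    mirrors — the fold-change pre-filter selects noise-inflated features,
    and correcting only over the tested set would not control the FDR) or
    "bh_tested" (BH over tested features only). ``significant`` means
    fdr < alpha.
    """
    mask1 = _as_mask(cells_group1, counts.shape[1])
    mask2 = _as_mask(cells_group2, counts.shape[1])
    if not mask1.any() or not mask2.any():
        raise ValidationError("both groups must be non-empty")
    if (mask1 & mask2).any():
        raise ValidationError("groups must be disjoint")
    C = sp.csr_matrix(counts)
    N = sp.csr_matrix(normalized)
    pct1 = np.asarray((C[:, mask1] > 0).mean(axis=1)).ravel()
    pct2 = np.asarray((C[:, mask2] > 0).mean(axis=1)).ravel()
    # fold change on de-logged normalized means
    e1 = np.asarray(np.expm1(N[:, mask1].toarray()).mean(axis=1)).ravel()
    e2 = np.asarray(np.expm1(N[:, mask2].toarray()).mean(axis=1)).ravel()
    lfc = log2_fold_change(e1, e2)

    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(lfc) >= logfc_threshold)
    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(
            columns=[
                "feature", "log2fc", "pct1", "pct2", "p_value", "fdr",
                "direction", "significant",
            ]
        )
    Xn = N[idx, :].toarray()
    p = _vectorized_wilcoxon(Xn, mask1, mask2)
    if p_adjust == "bonferroni_all":
        fdr = np.minimum(1.0, p * C.shape[0])
    elif p_adjust == "bh_tested":
        fdr = bh_adjust(p)
    else:
        raise ValidationError(f"unknown p_adjust {p_adjust!r}")
    out = pd.DataFrame(
        {
            "feature": [feature_ids[i] for i in idx],
            "log2fc": lfc[idx],
            "pct1": pct1[idx],
            "pct2": pct2[idx],
            "p_value": p,
            "fdr": fdr,
        }
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    out["significant"] = out["fdr"] < alpha
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def find_all_markers(
    counts: sp.spmatrix,
    normalized: sp.spmatrix,
    feature_ids: list[str],
    labels: np.ndarray,
    min_pct: float = 0.25,
    logfc_threshold: float = 0.25,
    alpha: float = 0.05,
    p_adjust: str = "bonferroni_all",
) -> pd.DataFrame:
    """One-vs-rest markers for every cluster with >= 2 cells."""
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("need >= 2 clusters")
    frames = []
    for c in uniq:
        g1 = labels == c
        if g1.sum() < 2:
            continue  # singleton cluster skipped
        res = find_markers(
            counts, normalized, feature_ids, g1, ~g1, min_pct, logfc_threshold,
            alpha, p_adjust,
        )
        res.insert(0, "cluster", c)
        frames.append(res)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def annotate_peaks(
    peaks: PeakSet,
    genes: pd.DataFrame,
    tss_region: tuple[int, int] = (-3000, 3000),
    exons: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Categorize each peak as promoter, exon, intron or distal_intergenic.

    Promoter wins when the peak overlaps the strand-aware window
    [TSS+tss_region[0], TSS+tss_region[1]] (upstream is 5'); then exon (if
    an exon table is given), then gene-body overlap (intron), else distal.
    """
    if len(genes) == 0:
        raise ValidationError("empty gene table")
    lo, hi = tss_region
    cats = []
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    ex_by_chrom = {c: g for c, g in exons.groupby("chrom")} if exons is not None else {}
    for iv in peaks.intervals:
        g = by_chrom.get(iv.chrom)
        cat = "distal_intergenic"
        if g is not None:
            tss = g["tss"].to_numpy()
            plus = (g["strand"] == "+").to_numpy()
            # strand-aware promoter window, half-open [w0, w1)
            w0 = np.where(plus, tss + lo, tss - hi)
            w1 = np.where(plus, tss + hi + 1, tss - lo + 1)
            if ((iv.start < w1) & (w0 < iv.end)).any():
                cat = "promoter"
            else:
                ex = ex_by_chrom.get(iv.chrom)
                in_exon = False
                if ex is not None:
                    s = ex["start"].to_numpy()
                    e = ex["end"].to_numpy()
                    in_exon = bool(((iv.start < e) & (s < iv.end)).any())
                if in_exon:
                    cat = "exon"
                else:
                    s = g["start"].to_numpy()
                    e = g["end"].to_numpy()
                    if ((iv.start < e) & (s < iv.end)).any():
                        cat = "intron"
        cats.append(cat)
    return pd.DataFrame({"peak": peaks.ids, "category": cats})


def geneset_ora(
    hits: list[str],
    universe: list[str],
    gene_sets: dict[str, list[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a hit list.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|set in universe|,
    n=|hits|); BH across sets.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    hit_set = set(hits)
    if not hit_set <= uni:
        raise ValidationError("hits must be a subset of the universe")
    N, n = len(uni), len(hit_set)
    rows = []
    for name, members in gene_sets.items():
        K = len(set(members) & uni)
        k = len(set(members) & hit_set)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K, "p_value": p})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] < alpha
    return out


def _as_mask(cells: np.ndarray, n: int) -> np.ndarray:
    cells = np.asarray(cells)
    if cells.dtype == bool:
        if len(cells) != n:
            raise ValidationError("boolean mask length mismatch")
        return cells
    mask = np.zeros(n, dtype=bool)
    mask[cells] = True
    return mask
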