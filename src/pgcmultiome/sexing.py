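"""Chromosomal-sex assignment from Y-linked module scores and chrY fragments.

Two module scorers are provided: a deterministic rank-based score (the
Mann-Whitney relative-rank formulation with a rank ceiling, bounded in
[0, 1]) used for the Y-linked signature, and a binned-control subtracted
score used for general signatures. Sex calls combine the module score with
the count of fragments falling in Y-chromosome peaks: a cell from a male
sample is demoted to ambiguous when it has no chrY-peak fragments or a
module score below the XY-reference cut; a cell from a female sample is
demoted when it has more than one chrY-peak fragment or a score above the
XX-reference cut.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .core import CountMatrix, PeakSet, ValidationError


def rank_module_score(
    normalized: np.ndarray | sp.spmatrix,
    feature_ids: list[str],
    signature: list[str],
    rank_ceiling: int = 1500,
) -> np.ndarray:
    """Rank-based per-cell signature score in [0, 1].

    Genes are ranked per cell by descending expression (average ranks for
    ties); ranks beyond ``rank_ceiling`` are clipped to ceiling+1. With
    U = sum(signature ranks) - n(n+1)/2, the score is
    1 - U / (n * (ceiling - n)), clipped into [0, 1]. A score of 1 means
    the signature occupies the top ranks; 0 means it sits entirely beyond
    the ceiling.
    """
    if not signature:
        raise ValidationError("empty signature")
    fi = {f: i for i, f in enumerate(feature_ids)}
    missing = [g for g in signature if g not in fi]
    if missing:
        raise ValidationError(f"signature genes absent: {missing}")
    X = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)
    n = len(signature)
    sig_idx = np.array([fi[g] for g in signature])
    # ranks of descending expression, per cell (column)
    ranks = rankdata(-X, axis=0, method="average")
    ranks = np.minimum(ranks, rank_ceiling + 1)
    u = ranks[sig_idx, :].sum(axis=0) - n * (n + 1) / 2
    score = 1.0 - u / (n * (rank_ceiling - n))
    return np.clip(score, 0.0, 1.0)


def control_module_score(
    normalized: np.ndarray | sp.spmatrix,
    feature_ids: list[str],
    signature: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Binned-control subtracted signature score.

    Genes are binned by average expression into ``n_bins``; for each
    signature gene, ``n_ctrl`` control genes are drawn with replacement from
    its bin; the score is mean(signature) - mean(controls) per cell.
    """
    if not signature:
        raise ValidationError("empty signature")
    fi = {f: i for i, f in enumerate(feature_ids)}
    missing = [g for g in signature if g not in fi]
    if missing:
        raise ValidationError(f"signature genes absent: {missing}")
    X = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)
    rng = np.random.default_rng(seed)
    avg = X.mean(axis=1)
    order = np.argsort(avg, kind="mergesort")
    bins = np.empty(len(avg), dtype=int)
    bins[order] = np.minimum(
        (np.arange(len(avg)) * n_bins) // max(len(avg), 1), n_bins - 1
    )
    sig_idx = np.array([fi[g] for g in signature])
    ctrl_rows = []
    for g in sig_idx:
        pool = np.flatnonzero(bins == bins[g])
        ctrl_rows.append(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_rows)
    return X[sig_idx, :].mean(axis=0) - X[ctrl_idx, :].mean(axis=0)


def chrY_fragment_counts(
    fragments: pd.DataFrame,
    chrY_peaks: PeakSet,
    chrY_region: tuple[int, int],
    cell_ids: list[str],
    y_chrom: str = "chrY",
) -> pd.Series:
    """Duplicate-weighted count of fragments overlapping any chrY peak
    inside the configured region, per cell. Half-open overlap: a fragment
    abutting a peak end is not counted."""
    lo, hi = chrY_region
    keep = [
        iv
        for iv in chrY_peaks.intervals
        if iv.chrom == y_chrom and iv.start < hi and iv.end > lo
    ]
    out = pd.Series(0, index=cell_ids, name="chrY_count", dtype=int)
    if not keep or len(fragments) == 0:
        return out
    frag = fragments[fragments["chrom"] == y_chrom]
    if len(frag) == 0:
        return out
    starts = np.array(sorted(iv.start for iv in keep))
    ends = np.array([iv.end for iv in sorted(keep, key=lambda x: x.start)])
    fs = frag["start"].to_numpy()
    fe = frag["end"].to_numpy()
    w = frag["count"].to_numpy()
    hit = np.zeros(len(frag), dtype=bool)
    # peaks are few; test each against all fragments
    for ps, pe in zip(starts, ends):
        hit |= (fs < pe) & (fe > ps)
    agg = (
        pd.DataFrame({"barcode": frag["barcode"].to_numpy(), "w": w * hit})
        .groupby("barcode", sort=False)["w"]
        .sum()
    )
    agg = agg.reindex(cell_ids, fill_value=0).astype(int)
    return pd.Series(agg.to_numpy(), index=cell_ids, name="chrY_count")


def assign_sex(
    scores: pd.Series,
    chrY_counts: pd.Series,
    claimed_sex: pd.Series,
    xy_reference: list[str],
    xx_reference: list[str],
    sd_factor: float = 1.0,
) -> pd.DataFrame:
    """Confirm or demote each cell's sample-of-origin sex claim.

    male_cut = mean(score | XY reference) - sd_factor * sd;
    female_cut = mean(score | XX reference) + sd_factor * sd.
    A claimed-male cell is demoted to ambiguous when its chrY-peak fragment
    count is 0 OR its score falls below male_cut; a claimed-female cell is
    demoted when its chrY count exceeds 1 OR its score rises above
    female_cut. Surviving cells keep the claim.
    """
    if len(xy_reference) < 2 or len(xx_reference) < 2:
        raise ValidationError("reference sets need >= 2 cells for an sd")
    male_cut = float(scores.loc[xy_reference].mean() - sd_factor * scores.loc[xy_reference].std(ddof=1))
    female_cut = float(scores.loc[xx_reference].mean() + sd_factor * scores.loc[xx_reference].std(ddof=1))
    calls = []
    for bc in scores.index:
        claim = claimed_sex.loc[bc]
        s = scores.loc[bc]
        y = int(chrY_counts.loc[bc])
        if claim == "XY":
            call = "ambiguous" if (y == 0 or s < male_cut) else "XY"
        elif claim == "XX":
            call = "ambiguous" if (y > 1 or s > female_cut) else "XX"
        else:
            call = "ambiguous"
        calls.append(call)
    return pd.DataFrame(
        {
            "barcode": scores.index,
            "module_score": scores.to_numpy(),
            "chrY_count": chrY_counts.loc[scores.index].to_numpy(),
            "claimed_sex": claimed_sex.loc[scores.index].to_numpy(),
            "call": calls,
            "male_cut": male_cut,
            "female_cut": female_cut,
        }
    ).reset_index(drop=True)
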