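"""Permutation-based ligand-receptor interaction analysis.

Interactions between a sender cluster (ligand side) and a receiver cluster
(receptor side) are scored as the mean of the two cluster-level complex
means, where a heteromeric complex is summarized by its least-expressed
subunit and gated to zero when any subunit is detected in fewer than
``min_frac`` of the cluster's cells. Significance comes from permuting the
cluster labels over the union of the two clusters; the permutation p uses
+1 smoothing so p > 0 always.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import ValidationError


def parse_lr_table(lr: pd.DataFrame) -> list[dict]:
    """Expand an LR table (pair, ligand, receptor, pathway) with
    comma-separated subunit lists into pair records."""
    records = []
    for _, r in lr.iterrows():
        lig = [g.strip() for g in str(r["ligand"]).split(",") if g.strip()]
        rec = [g.strip() for g in str(r["receptor"]).split(",") if g.strip()]
        if not lig or not rec:
            raise ValidationError(f"pair {r['pair']}: empty subunit list")
        records.append(
            {
                "pair": r["pair"],
                "ligand": lig,
                "receptor": rec,
                "pathway": r.get("pathway", ""),
            }
        )
    return records


def cluster_complex_mean(
    normalized: np.ndarray,
    feature_ids: list[str],
    cell_mask: np.ndarray,
    subunits: list[str],
    min_frac: float = 0.1,
) -> tuple[float, float]:
    """Minimum-subunit cluster mean with the expression-fraction gate.

    Returns (complex mean, minimum detected fraction across subunits); the
    mean is 0 when any subunit is expressed in < min_frac of the cluster.
    """
    fi = {f: i for i, f in enumerate(feature_ids)}
    missing = [g for g in subunits if g not in fi]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    idx = [fi[g] for g in subunits]
    X = normalized[idx][:, cell_mask]
    means = X.mean(axis=1)
    fracs = (X > 0).mean(axis=1)
    complex_mean = float(means.min())
    min_frac_obs = float(fracs.min())
    if min_frac_obs < min_frac:
        complex_mean = 0.0
    return complex_mean, min_frac_obs


def interaction_test(
    normalized: np.ndarray | sp.spmatrix,
    feature_ids: list[str],
    sender_mask: np.ndarray,
    receiver_mask: np.ndarray,
    pair: dict,
    n_perm: int = 1000,
    min_frac: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Permutation test of one ligand-receptor pair.

    statistic = (ligand complex mean in sender + receptor complex mean in
    receiver) / 2; the null permutes sender/receiver labels over the union;
    p = (1 + #{null >= observed}) / (1 + n_perm). Pairs gated to zero on
    either side get p = 1.
    """
    sender_mask = np.asarray(sender_mask, dtype=bool)
    receiver_mask = np.asarray(receiver_mask, dtype=bool)
    if (sender_mask & receiver_mask).any():
        raise ValidationError("sender and receiver clusters overlap")
    n_s, n_r = int(sender_mask.sum()), int(receiver_mask.sum())
    if min(n_s, n_r) < 10:
        raise ValidationError("clusters need >= 10 cells")
    X = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)

    lig_mean, lig_frac = cluster_complex_mean(
        X, feature_ids, sender_mask, pair["ligand"], min_frac
    )
    rec_mean, rec_frac = cluster_complex_mean(
        X, feature_ids, receiver_mask, pair["receptor"], min_frac
    )
    observed = (lig_mean + rec_mean) / 2
    gated = lig_mean == 0.0 or rec_mean == 0.0

    if gated or n_perm == 0:
        p = 1.0
    else:
        fi = {f: i for i, f in enumerate(feature_ids)}
        lig_idx = [fi[g] for g in pair["ligand"]]
        rec_idx = [fi[g] for g in pair["receptor"]]
        union = np.flatnonzero(sender_mask | receiver_mask)
        Xl = X[np.ix_(lig_idx, union)]
        Xr = X[np.ix_(rec_idx, union)]
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(len(union))
            s_cols = perm[:n_s]
            r_cols = perm[n_s:]
            null_stat = (
                Xl[:, s_cols].mean(axis=1).min()
                + Xr[:, r_cols].mean(axis=1).min()
            ) / 2
            if null_stat >= observed - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_perm)

    return {
        "pair": pair["pair"],
        "pathway": pair.get("pathway", ""),
        "interaction_mean": observed,
        "p_value": p,
        "pct_ligand": lig_frac,
        "pct_receptor": rec_frac,
        "significant": bool(p < alpha and not gated),
    }


def test_condition(
    normalized,
    feature_ids: list[str],
    sender_mask: np.ndarray,
    receiver_mask: np.ndarray,
    pairs: list[dict],
    n_perm: int = 1000,
    min_frac: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairs for one (sender, receiver) condition; pairs with genes
    absent from the matrix are skipped with a reason row."""
    rows = []
    for k, pair in enumerate(pairs):
        try:
            rows.append(
                interaction_test(
                    normalized, feature_ids, sender_mask, receiver_mask,
                    pair, n_perm, min_frac, alpha, seed + k,
                )
            )
        except ValidationError as exc:
            if "absent" in str(exc):
                rows.append(
                    {
                        "pair": pair["pair"], "pathway": pair.get("pathway", ""),
                        "interaction_mean": np.nan, "p_value": np.nan,
                        "pct_ligand": np.nan, "pct_receptor": np.nan,
                        "significant": False,
                    }
                )
            else:
                raise
    return pd.DataFrame(rows)


def count_interactions(
    results_by_condition: dict[str, pd.DataFrame], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Counts of significant pairs per condition and pathway, plus the
    XX-only / XY-only / shared partition per stage.

    Condition keys are '<sex>_<stage>'.
    """
    cond_rows, path_rows = [], []
    sig_sets: dict[str, set] = {}
    for cond, df in results_by_condition.items():
        sig = df[(df["p_value"] < alpha) & df["significant"]]
        sig_sets[cond] = set(sig["pair"])
        cond_rows.append({"condition": cond, "n_significant": len(sig_sets[cond])})
        for pathway, grp in sig.groupby("pathway"):
            path_rows.append(
                {"condition": cond, "pathway": pathway, "n_significant": len(grp)}
            )
    stages = sorted({c.split("_", 1)[1] for c in results_by_condition})
    venn_rows = []
    for stage in stages:
        xx = sig_sets.get(f"XX_{stage}", set())
        xy = sig_sets.get(f"XY_{stage}", set())
        venn_rows.append(
            {
                "stage": stage,
                "xx_only": len(xx - xy),
                "xy_only": len(xy - xx),
                "shared": len(xx & xy),
            }
        )
    return (
        pd.DataFrame(cond_rows),
        pd.DataFrame(path_rows, columns=["condition", "pathway", "n_significant"]),
        pd.DataFrame(venn_rows, columns=["stage", "xx_only", "xy_only", "shared"]),
    )


def means_dotplot_table(
    normalized,
    feature_ids: list[str],
    cluster_masks: dict[str, np.ndarray],
    pairs: list[dict],
    min_frac: float = 0.1,
) -> pd.DataFrame:
    """Dotplot-ready complex means per (pair side, cluster)."""
    X = normalized.toarray() if sp.issparse(normalized) else np.asarray(normalized)
    rows = []
    for pair in pairs:
        for side, genes in (("ligand", pair["ligand"]), ("receptor", pair["receptor"])):
            for cname, mask in cluster_masks.items():
                try:
                    m, f = cluster_complex_mean(X, feature_ids, mask, genes, min_frac)
                except ValidationError:
                    m, f = np.nan, np.nan
                rows.append(
                    {
                        "pair": pair["pair"], "side": side, "cluster": cname,
                        "complex_mean": m, "min_pct": f,
                    }
                )
    return pd.DataFrame(rows)
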