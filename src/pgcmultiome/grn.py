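"""TF-candidate triage and regulatory-network assembly.

The triage keeps a TF when it (a) is differentially expressed between
sexes, (b) is germline-enriched (up in PGCs vs somatic cells), (c) has its
motif enriched in differentially accessible peaks linked to DEGs, and
(d) shows positive mean motif-activity z in the focal population. Edges
TF -> target are created where a significant peak-gene link's peak carries
the TF's motif; duplicate edges keep the best-p peak.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ValidationError


def triage_tfs(
    sex_de: pd.DataFrame,
    germ_de: pd.DataFrame,
    enrichment: pd.DataFrame,
    deviation_z_by_population: pd.DataFrame,
    tf_motif_map: dict[str, str],
    focal_population: str | dict[str, str],
    alpha: float = 0.05,
    de_logfc: float = 0.25,
) -> pd.DataFrame:
    """Score every mapped TF against the four triage criteria.

    ``sex_de`` and ``germ_de`` are find_markers tables (feature, log2fc,
    fdr); ``germ_de`` must be oriented PGC-vs-soma so positive log2fc means
    germline-enriched. ``enrichment`` is a motif_enrichment table;
    ``deviation_z_by_population`` has motifs as rows and populations as
    columns (mean z). ``focal_population`` may be one column name for all
    TFs or a per-TF mapping. TFs without a motif mapping are skipped.
    """
    sex_idx = sex_de.set_index("feature")
    germ_idx = germ_de.set_index("feature")
    enr_idx = enrichment.set_index("motif_id")
    rows = []
    for tf, motif in tf_motif_map.items():
        if motif not in enr_idx.index:
            continue
        de_row = sex_idx.loc[tf] if tf in sex_idx.index else None
        is_de = bool(
            de_row is not None
            and de_row["fdr"] < alpha
            and abs(de_row["log2fc"]) >= de_logfc
        )
        g_row = germ_idx.loc[tf] if tf in germ_idx.index else None
        is_germ = bool(
            g_row is not None and g_row["fdr"] < alpha and g_row["log2fc"] > 0
        )
        enr = enr_idx.loc[motif]
        is_enr = bool(enr["p_value"] < alpha)
        focal = (
            focal_population.get(tf) if isinstance(focal_population, dict) else focal_population
        )
        mean_z = float(
            deviation_z_by_population.loc[motif, focal]
            if (focal in deviation_z_by_population.columns and motif in deviation_z_by_population.index)
            else np.nan
        )
        pos_z = bool(np.isfinite(mean_z) and mean_z > 0)
        reasons = []
        if not is_de:
            reasons.append("not_sex_de")
        if not is_germ:
            reasons.append("not_germline_enriched")
        if not is_enr:
            reasons.append("motif_not_enriched")
        if not pos_z:
            reasons.append("nonpositive_activity")
        rows.append(
            {
                "tf": tf,
                "motif_id": motif,
                "is_de_between_sexes": is_de,
                "sex_log2fc": float(de_row["log2fc"]) if de_row is not None else np.nan,
                "is_germline_enriched": is_germ,
                "motif_enriched": is_enr,
                "enrichment_p": float(enr["p_value"]),
                "mean_motif_activity_z": mean_z,
                "passes_all": is_de and is_germ and is_enr and pos_z,
                "fail_reasons": ";".join(reasons),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("enrichment_p", kind="mergesort").reset_index(drop=True)
    return out


def assign_targets(
    candidates: pd.DataFrame,
    links_to_degs: pd.DataFrame,
    hits: pd.DataFrame,
    degs: list[str],
) -> pd.DataFrame:
    """Build TF -> target edges from motif hits inside significant links.

    An edge exists when a retained link's peak contains >= 1 hit of the
    TF's motif; duplicates collapse to the best-p supporting peak. The
    returned frame carries per-edge link statistics and motif position.
    """
    if len(candidates) == 0:
        return pd.DataFrame(
            columns=["tf", "target", "peak", "motif_id", "offset", "z_score", "p_value"]
        )
    sig = links_to_degs[links_to_degs["retained"]] if "retained" in links_to_degs else links_to_degs
    hit_key = hits.groupby(["peak", "motif_id"])["offset"].min()
    rows = []
    for _, cand in candidates[candidates["passes_all"]].iterrows():
        motif = cand["motif_id"]
        for _, ln in sig.iterrows():
            key = (ln["peak"], motif)
            if key in hit_key.index:
                rows.append(
                    {
                        "tf": cand["tf"],
                        "target": ln["gene"],
                        "peak": ln["peak"],
                        "motif_id": motif,
                        "offset": int(hit_key.loc[key]),
                        "z_score": ln["z_score"],
                        "p_value": ln["p_value"],
                    }
                )
    edges = pd.DataFrame(
        rows, columns=["tf", "target", "peak", "motif_id", "offset", "z_score", "p_value"]
    )
    if len(edges):
        edges = (
            edges.sort_values("p_value", kind="mergesort")
            .drop_duplicates(["tf", "target"], keep="first")
            .sort_values(["tf", "target"], kind="mergesort")
            .reset_index(drop=True)
        )
    return edges


def cross_regulation(
    candidates: pd.DataFrame,
    links: pd.DataFrame,
    hits: pd.DataFrame,
    promoter_peaks_by_gene: dict[str, list[str]],
) -> pd.DataFrame:
    """TF x TF incidence: (A, B) = 1 when A's motif sits in a retained
    linked peak of gene B or in B's promoter peaks. Self-regulation is
    reported on the diagonal."""
    tfs = candidates["tf"].tolist()
    motif_of = dict(zip(candidates["tf"], candidates["motif_id"]))
    sig = links[links["retained"]] if "retained" in links else links
    peaks_of_gene = sig.groupby("gene")["peak"].agg(set) if len(sig) else pd.Series(dtype=object)
    hit_pairs = set(zip(hits["peak"], hits["motif_id"]))
    M = pd.DataFrame(0, index=tfs, columns=tfs, dtype=int)
    for a in tfs:
        motif = motif_of[a]
        for b in tfs:
            peaks = set(promoter_peaks_by_gene.get(b, []))
            if b in peaks_of_gene.index:
                peaks |= peaks_of_gene[b]
            if any((p, motif) in hit_pairs for p in peaks):
                M.loc[a, b] = 1
    return M


def network_summary(
    edges: pd.DataFrame, degs: list[str], links: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-TF target coverage of linked DEGs, plus pairwise target overlaps.

    The denominator is the number of DEGs having >= 1 retained link; the
    percentage is NaN-flagged when that denominator is zero.
    """
    sig = links[links["retained"]] if "retained" in links else links
    linked_degs = set(sig["gene"]) & set(degs)
    denom = len(linked_degs)
    targets_of = (
        edges.groupby("tf")["target"].agg(set) if len(edges) else pd.Series(dtype=object)
    )
    rows = []
    for tf in sorted(targets_of.index):
        n_t = len(targets_of[tf])
        rows.append(
            {
                "tf": tf,
                "n_targets": n_t,
                "linked_degs": denom,
                "pct_of_linked_degs": 100.0 * n_t / denom if denom else np.nan,
            }
        )
    summary = pd.DataFrame(rows, columns=["tf", "n_targets", "linked_degs", "pct_of_linked_degs"])
    tfs = sorted(targets_of.index)
    overlap = pd.DataFrame(0, index=tfs, columns=tfs, dtype=int)
    for a in tfs:
        for b in tfs:
            overlap.loc[a, b] = len(targets_of[a] & targets_of[b])
    return summary, overlap


def to_networkx(edges: pd.DataFrame):
    """GraphML-ready directed network of the TF -> target edges."""
    import networkx as nx

    g = nx.DiGraph()
    for _, e in edges.iterrows():
        g.add_edge(
            e["tf"],
            e["target"],
            peak=e["peak"],
            motif_id=e["motif_id"],
            p_value=float(e["p_value"]),
        )
    for n in g.nodes:
        is_tf = n in set(edges["tf"])
        is_target = n in set(edges["target"])
        g.nodes[n]["role"] = "both" if (is_tf and is_target) else ("tf" if is_tf else "target")
    return g
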