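"""Stage orchestration: simulate, qc, sex, cluster, de, link, motif, grn,
comm — each reading the dataset directory plus earlier stage outputs and
writing deterministic TSV tables into the output directory.

Outputs are a pure function of (inputs, config, seed): every random step
draws from a seed derived from the pipeline seed, and all tables are
written with a fixed float format.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import comm as comm_mod
from . import differential as de_mod
from . import embed, grn, links as links_mod, motifs as motif_mod, qc, sexing
from . import io as pio
from .config import DEFAULT_MARKERS, PipelineConfig
from .core import CountMatrix, PeakSet, ValidationError
from .simulate import SynthConfig, simulate_multiome, write_dataset, load_dataset

log = logging.getLogger("pgcmultiome")

STAGE_ORDER = ["simulate", "qc", "sex", "cluster", "de", "link", "motif", "grn", "comm"]


class PipelineState:
    """In-memory carry-over between stages of one `run_pipeline` call."""

    def __init__(self, data_dir: Path, outdir: Path, config: PipelineConfig):
        self.data_dir = Path(data_dir)
        self.outdir = Path(outdir)
        self.config = config
        self.cache: dict = {}

    def dataset(self):
        if "dataset" not in self.cache:
            if not (self.data_dir / "rna_matrix.mtx").exists():
                raise ValidationError(
                    "stage requires a simulated dataset; run 'simulate' first"
                )
            self.cache["dataset"] = load_dataset(self.data_dir)
        return self.cache["dataset"]


def run_pipeline(
    stages: list[str],
    data_dir: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    synth_config: SynthConfig | None = None,
    seed: int = 0,
) -> Path:
    """Run the requested stages in canonical order; 'all' runs everything."""
    config = config or PipelineConfig(seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages == ["all"]:
        stages = STAGE_ORDER
    unknown = [s for s in stages if s not in STAGE_ORDER]
    if unknown:
        raise ValidationError(f"unknown stages: {unknown}")
    state = PipelineState(Path(data_dir), outdir, config)
    runners = {
        "simulate": lambda: stage_simulate(state, synth_config, seed),
        "qc": lambda: stage_qc(state),
        "sex": lambda: stage_sex(state),
        "cluster": lambda: stage_cluster(state, seed),
        "de": lambda: stage_de(state),
        "link": lambda: stage_link(state, seed),
        "motif": lambda: stage_motif(state, seed),
        "grn": lambda: stage_grn(state),
        "comm": lambda: stage_comm(state, seed),
    }
    for s in STAGE_ORDER:
        if s in stages:
            log.info("stage %s", s)
            runners[s]()
    return outdir


# ---------------------------------------------------------------------------


def stage_simulate(state: PipelineState, synth_config: SynthConfig | None, seed: int) -> None:
    ds = simulate_multiome(synth_config or SynthConfig(), seed)
    write_dataset(ds, state.data_dir)
    state.cache["dataset"] = ds
    sd = state.outdir / "simulate"
    sd.mkdir(exist_ok=True)
    pio.write_table(
        pd.DataFrame(
            {
                "quantity": ["n_cells", "n_genes", "n_peaks", "n_fragments"],
                "value": [
                    len(ds.rna.cell_ids), len(ds.rna.feature_ids),
                    len(ds.atac.feature_ids), len(ds.fragments),
                ],
            }
        ),
        sd / "summary.tsv",
    )


def _require(state: PipelineState, stage: str, fname: str) -> Path:
    p = state.outdir / fname
    if not p.exists():
        raise ValidationError(f"stage '{stage}' requires {fname}; run earlier stages")
    return p


def stage_qc(state: PipelineState) -> None:
    ds = state.dataset()
    cfg = state.config
    if len(ds.fragments) == 0:
        raise ValidationError("stage 'qc' requires a fragments file in the dataset")
    qdir = state.outdir / "qc"
    qdir.mkdir(exist_ok=True)

    metrics = qc.compute_qc_metrics(ds.rna, ds.atac, ds.fragments, ds.genes)
    retained, rule_counts = qc.filter_cells(metrics, cfg)
    log.info("qc: %d/%d cells retained", len(retained), len(metrics))
    pio.write_table(metrics, qdir / "cell_metrics.tsv")
    pio.write_table(rule_counts, qdir / "filter_counts.tsv")

    types = qc.call_cell_types(ds.rna, DEFAULT_MARKERS)
    pio.write_table(types, qdir / "cell_types.tsv")

    standard = {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY", "chrM"}
    peaks_kept, keep_mask = qc.filter_peaks(
        ds.peaks, standard, None, cfg.peak_width_min, cfg.peak_width_max
    )
    log.info("qc: %d/%d peaks retained", len(peaks_kept), len(ds.peaks))
    pio.write_peaks_bed(peaks_kept, qdir / "peaks_retained.bed")
    pd.DataFrame({"barcode": retained}).to_csv(
        qdir / "cells_retained.tsv", sep="\t", index=False
    )


def _qc_products(state: PipelineState, stage: str = "analysis"):
    ds = state.dataset()
    cfg = state.config
    qdir = state.outdir / "qc"
    retained = pd.read_csv(_require(state, stage, "qc/cells_retained.tsv"), sep="\t")[
        "barcode"
    ].tolist()
    types = pd.read_csv(qdir / "cell_types.tsv", sep="\t").set_index("barcode")
    kept_bed = pio.read_peaks_bed(qdir / "peaks_retained.bed")
    kept_ids = set(
        f"{iv.chrom}:{iv.start}-{iv.end}" for iv in kept_bed.intervals
    )
    keep_idx = [i for i, pid in enumerate(ds.peaks.ids) if pid in kept_ids]
    peaks = ds.peaks.subset(keep_idx)
    atac = ds.atac.subset_features([ds.peaks.ids[i] for i in keep_idx]).subset_cells(retained)
    rna = qc.drop_mito_features(ds.rna, ds.genes).subset_cells(retained)
    samples = pd.read_csv(state.data_dir / "samples.tsv", sep="\t").set_index("barcode")
    return rna, atac, peaks, types, samples, retained


def stage_sex(state: PipelineState) -> None:
    ds = state.dataset()
    cfg = state.config
    if len(ds.fragments) == 0:
        raise ValidationError("stage 'sex' requires fragments in the dataset")
    rna, atac, peaks, types, samples, retained = _qc_products(state, "sex")
    sdir = state.outdir / "sex"
    sdir.mkdir(exist_ok=True)

    norm = embed.lognormalize(rna.values)
    score = sexing.rank_module_score(
        norm, rna.feature_ids, [g for g in cfg.y_genes if g in set(rna.feature_ids)],
        cfg.rank_ceiling,
    )
    scores = pd.Series(score, index=rna.cell_ids)

    chry_peaks_idx = [
        i for i, iv in enumerate(peaks.intervals) if iv.chrom == "chrY"
    ]
    chry = peaks.subset(chry_peaks_idx) if chry_peaks_idx else PeakSet([], np.array([]), np.array([]), [])
    ycounts = sexing.chrY_fragment_counts(
        ds.fragments, chry, cfg.chrY_region, rna.cell_ids
    )

    claimed = samples["sex"].reindex(rna.cell_ids)
    stage_of = samples["stage"].reindex(rna.cell_ids)
    xy_ref = [b for b in rna.cell_ids if claimed[b] == "XY" and stage_of[b] == "E13.5"]
    xx_ref = [b for b in rna.cell_ids if claimed[b] == "XX" and stage_of[b] == "E13.5"]
    calls = sexing.assign_sex(scores, ycounts, claimed, xy_ref, xx_ref)
    n_conf = (calls["call"] != "ambiguous").sum()
    log.info("sex: %d/%d cells confirmed", n_conf, len(calls))
    pio.write_table(calls, sdir / "sex_calls.tsv")


def _analysis_cells(state: PipelineState):
    """Cells passing QC with confirmed sex; returns matrices restricted to
    them plus per-cell annotations."""
    rna, atac, peaks, types, samples, retained = _qc_products(state)
    calls = pd.read_csv(_require(state, "analysis", "sex/sex_calls.tsv"), sep="\t").set_index("barcode")
    keep = [b for b in rna.cell_ids if calls.loc[b, "call"] != "ambiguous"]
    rna = rna.subset_cells(keep)
    atac = atac.subset_cells(keep)
    ann = pd.DataFrame(
        {
            "barcode": keep,
            "sex": calls.loc[keep, "call"].to_numpy(),
            "stage": samples.loc[keep, "stage"].to_numpy(),
            "cell_type": types.loc[keep, "label"].to_numpy(),
        }
    ).set_index("barcode")
    return rna, atac, peaks, ann


def stage_cluster(state: PipelineState, seed: int) -> None:
    cfg = state.config
    rna, atac, peaks, ann = _analysis_cells(state)
    cdir = state.outdir / "cluster"
    cdir.mkdir(exist_ok=True)

    pgc = ann.index[ann["cell_type"] == "PGC"].tolist()
    if len(pgc) < cfg.knn_k + 1:
        raise ValidationError("stage 'cluster': too few PGCs after filtering")
    rna_p = rna.subset_cells(pgc)
    atac_p = atac.subset_cells(pgc)

    norm = embed.lognormalize(rna_p.values)
    rna_lat = embed.pca(norm, rna_p.feature_ids, cfg.n_hvg, cfg.n_pcs)
    rna_lat.default_dims = list(range(min(cfg.rna_dims, rna_lat.coords.shape[1])))
    atac_lat = embed.tfidf_lsi(atac_p.values, cfg.lsi_dims, seed=seed)

    weights, joint_idx, joint_dist = embed.weighted_joint_neighbors(
        rna_lat, atac_lat, cfg.knn_k
    )
    joint = embed.joint_embedding(rna_lat, atac_lat, weights)
    clusters = embed.snn_cluster(joint, None, cfg.knn_k, cfg.resolution, seed)
    log.info("cluster: %d clusters over %d PGCs", clusters.labels.max() + 1, len(pgc))

    root = np.flatnonzero(ann.loc[pgc, "stage"].to_numpy() == "E11.5")
    pt = embed.mst_pseudotime(joint, clusters.labels, root)
    emb2 = embed.embed_2d(joint, seed)

    pio.write_table(
        pd.DataFrame(
            rna_lat.coords[:, rna_lat.default_dims],
            columns=[f"PC{i+1}" for i in rna_lat.default_dims],
        ).assign(barcode=pgc),
        cdir / "rna_latent.tsv",
    )
    pio.write_table(
        pd.DataFrame(
            atac_lat.coords[:, atac_lat.default_dims],
            columns=[f"LSI{i+1}" for i in atac_lat.default_dims],
        ).assign(barcode=pgc),
        cdir / "atac_latent.tsv",
    )
    pio.write_table(
        weights.assign(barcode=pgc), cdir / "weights.tsv"
    )
    pio.write_table(
        pd.DataFrame(
            {
                "barcode": pgc,
                "cluster": clusters.labels,
                "pseudotime": pt.pseudotime,
                "umap1": emb2[:, 0],
                "umap2": emb2[:, 1],
            }
        ),
        cdir / "clusters.tsv",
    )
    pio.write_table(
        pd.DataFrame(
            {
                "root_cluster": [pt.root_cluster],
                "branch_nodes": [",".join(map(str, pt.branch_nodes))],
                "terminal_nodes": [",".join(map(str, pt.terminal_nodes))],
            }
        ),
        cdir / "trajectory.tsv",
    )


def stage_de(state: PipelineState) -> None:
    cfg = state.config
    rna, atac, peaks, ann = _analysis_cells(state)
    ddir = state.outdir / "de"
    ddir.mkdir(exist_ok=True)

    norm_rna = embed.lognormalize(rna.values)
    norm_atac = embed.lognormalize(atac.values)
    is_pgc = (ann["cell_type"] == "PGC").to_numpy()

    deg_frames, dap_frames = [], []
    for stg in sorted(ann["stage"].unique()):
        m_stage = (ann["stage"] == stg).to_numpy()
        g_xx = m_stage & is_pgc & (ann["sex"] == "XX").to_numpy()
        g_xy = m_stage & is_pgc & (ann["sex"] == "XY").to_numpy()
        if g_xx.sum() < 3 or g_xy.sum() < 3:
            log.warning("de: skipping stage %s (too few PGCs)", stg)
            continue
        degs = de_mod.find_markers(
            rna.values, norm_rna, rna.feature_ids, g_xx, g_xy,
            cfg.de_min_pct, cfg.de_logfc, cfg.alpha,
        )
        degs.insert(0, "stage", stg)
        deg_frames.append(degs)
        daps = de_mod.find_markers(
            atac.values, norm_atac, atac.feature_ids, g_xx, g_xy,
            cfg.dap_min_pct, cfg.dap_logfc, cfg.alpha,
        )
        daps.insert(0, "stage", stg)
        dap_frames.append(daps)
    pio.write_table(pd.concat(deg_frames, ignore_index=True), ddir / "degs.tsv")
    pio.write_table(pd.concat(dap_frames, ignore_index=True), ddir / "daps.tsv")

    # germline enrichment: PGCs vs pooled somatic cells
    soma = (~is_pgc) & (ann["cell_type"] != "excluded").to_numpy()
    germ = de_mod.find_markers(
        rna.values, norm_rna, rna.feature_ids, is_pgc, soma,
        cfg.de_min_pct, cfg.de_logfc, cfg.alpha,
    )
    pio.write_table(germ, ddir / "germline_enrichment.tsv")

    annot = de_mod.annotate_peaks(peaks, state.dataset().genes, cfg.tss_region)
    pio.write_table(annot, ddir / "peak_annotation.tsv")


def stage_link(state: PipelineState, seed: int) -> None:
    cfg = state.config
    rna, atac, peaks, ann = _analysis_cells(state)
    ldir = state.outdir / "link"
    ldir.mkdir(exist_ok=True)

    genes = state.dataset().genes
    genes = genes[genes["gene"].isin(set(rna.feature_ids))]
    pairs = links_mod.candidate_pairs(peaks, genes, cfg.link_distance)
    log.info("link: %d candidate pairs", len(pairs))

    # links are computed within each sex's PGCs so sex-differential
    # abundance cannot masquerade as peak-gene coupling
    frames = []
    for k, sex in enumerate(("XX", "XY")):
        pgc = ann.index[
            (ann["cell_type"] == "PGC") & (ann["sex"] == sex)
        ].tolist()
        if len(pgc) < 10:
            log.warning("link: skipping sex %s (too few PGCs)", sex)
            continue
        rna_p = rna.subset_cells(pgc)
        atac_p = atac.subset_cells(pgc)
        res = links_mod.link_peaks(
            embed.lognormalize(atac_p.values),
            embed.lognormalize(rna_p.values),
            atac_p.feature_ids,
            rna_p.feature_ids,
            pairs,
            peaks,
            cfg.n_background,
            cfg.link_p,
            seed + 11 + k,
        )
        res.insert(0, "link_sex", sex)
        log.info("link: %s %d retained", sex, int(res["retained"].sum()))
        frames.append(res)
    res = pd.concat(frames, ignore_index=True)
    pio.write_table(res, ldir / "links.tsv")

    degs = pd.read_csv(_require(state, "link", "de/degs.tsv"), sep="\t")
    daps = pd.read_csv(state.outdir / "de" / "daps.tsv", sep="\t")
    sig_degs = degs.loc[degs["significant"], "feature"].unique().tolist()
    sig_daps = daps.loc[daps["significant"], "feature"].unique().tolist()
    frac = links_mod.dap_deg_overlap(sig_daps, sig_degs, res)
    pio.write_table(
        pd.DataFrame({"statistic": ["deg_with_da_peak_fraction"], "value": [frac]}),
        ldir / "dap_deg_overlap.tsv",
    )


def stage_motif(state: PipelineState, seed: int) -> None:
    cfg = state.config
    ds = state.dataset()
    rna, atac, peaks, ann = _analysis_cells(state)
    mdir = state.outdir / "motif"
    mdir.mkdir(exist_ok=True)

    pwms = [
        motif_mod.pfm_to_pwm(m["pfm"], m["id"], m["name"]) for m in ds.motifs
    ]
    seqs = {pid: ds.peak_sequences[pid] for pid in peaks.ids if pid in ds.peak_sequences}
    hit_matrix, hits = motif_mod.build_hit_matrix(
        seqs, pwms, peaks.ids, cfg.motif_threshold_frac
    )
    pio.write_table(hits, mdir / "motif_hits.tsv")

    links = pd.read_csv(_require(state, "motif", "link/links.tsv"), sep="\t")
    degs = pd.read_csv(_require(state, "motif", "de/degs.tsv"), sep="\t")
    daps = pd.read_csv(state.outdir / "de" / "daps.tsv", sep="\t")
    focal_stage = "E13.5" if (degs["stage"] == "E13.5").any() else degs["stage"].iloc[0]
    sig_degs = degs.loc[
        degs["significant"] & (degs["stage"] == focal_stage), "feature"
    ].unique().tolist()
    sig_daps = set(
        daps.loc[daps["significant"] & (daps["stage"] == focal_stage), "feature"]
    )
    sig_links = links[links["retained"] & links["gene"].isin(set(sig_degs))]
    fg_ids = sorted(set(sig_links["peak"]) & sig_daps)
    pi = {p: i for i, p in enumerate(peaks.ids)}
    fg = np.array([pi[p] for p in fg_ids], dtype=int)
    if fg.size == 0:
        raise ValidationError("stage 'motif': no DA peaks linked to DEGs")
    n_bg = min(2000, len(peaks) - fg.size)
    bg = motif_mod.matched_background_peaks(fg, peaks, n_bg, seed + 23)
    enr = motif_mod.motif_enrichment(
        fg, bg, hit_matrix, [p.motif_id for p in pwms], cfg.alpha
    )
    pio.write_table(enr, mdir / "enrichment.tsv")

    dev = motif_mod.chromvar_deviations(
        atac.values, hit_matrix, peaks, [p.motif_id for p in pwms],
        atac.cell_ids, cfg.chromvar_iterations, seed + 31,
    )
    group = ann["cell_type"].astype(str) + "_" + ann["sex"].astype(str)
    zdf = pd.DataFrame(dev.z, index=dev.motif_ids, columns=dev.cell_ids)
    pop_means = zdf.T.groupby(group.reindex(dev.cell_ids)).mean().T
    pop_means.index.name = "motif_id"
    pio.write_table(pop_means.reset_index(), mdir / "deviation_z_by_population.tsv")
    pio.write_table(
        zdf.reset_index().rename(columns={"index": "motif_id"}),
        mdir / "deviations_z.tsv",
    )


def stage_grn(state: PipelineState) -> None:
    cfg = state.config
    ds = state.dataset()
    gdir = state.outdir / "grn"
    gdir.mkdir(exist_ok=True)

    degs = pd.read_csv(_require(state, "grn", "de/degs.tsv"), sep="\t")
    germ = pd.read_csv(_require(state, "grn", "de/germline_enrichment.tsv"), sep="\t")
    enr = pd.read_csv(_require(state, "grn", "motif/enrichment.tsv"), sep="\t")
    popz = pd.read_csv(
        _require(state, "grn", "motif/deviation_z_by_population.tsv"), sep="\t"
    ).set_index("motif_id")
    links = pd.read_csv(_require(state, "grn", "link/links.tsv"), sep="\t")
    hits = pd.read_csv(_require(state, "grn", "motif/motif_hits.tsv"), sep="\t")

    focal_stage = "E13.5" if (degs["stage"] == "E13.5").any() else degs["stage"].iloc[0]
    sex_de = degs[degs["stage"] == focal_stage]
    tf_map = {m["name"]: m["id"] for m in ds.motifs}

    # focal population follows each TF's favored sex (XX when log2fc > 0;
    # the sex contrast is oriented XX vs XY)
    sex_idx = sex_de.set_index("feature")
    focal = {
        tf: (
            "PGC_XX"
            if tf in sex_idx.index and sex_idx.loc[tf, "log2fc"] > 0
            else "PGC_XY"
        )
        for tf in tf_map
    }
    cands = grn.triage_tfs(
        sex_de, germ, enr, popz, tf_map, focal, cfg.alpha, cfg.de_logfc
    )
    pio.write_table(cands, gdir / "tf_candidates.tsv")

    sig_degs = sex_de.loc[sex_de["significant"], "feature"].unique().tolist()
    links_degs = links_mod.links_for_genes(links[links["retained"]], sig_degs)
    edges = grn.assign_targets(cands, links_degs, hits, sig_degs)
    pio.write_table(edges, gdir / "network_edges.tsv")

    annot = pd.read_csv(state.outdir / "de" / "peak_annotation.tsv", sep="\t")
    promoter_peaks = annot[annot["category"] == "promoter"]
    promo_by_gene = _promoter_peaks_by_gene(ds, promoter_peaks["peak"].tolist())
    cross = grn.cross_regulation(cands, links, hits, promo_by_gene)
    cross.index.name = "tf"
    pio.write_table(cross.reset_index(), gdir / "cross_regulation.tsv")

    summary, overlap = grn.network_summary(edges, sig_degs, links)
    pio.write_table(summary, gdir / "summary.tsv")
    overlap.index.name = "tf"
    pio.write_table(overlap.reset_index(), gdir / "target_overlap.tsv")


def _promoter_peaks_by_gene(ds, promoter_peak_ids: list[str]) -> dict[str, list[str]]:
    """Map genes to promoter-overlapping peaks by TSS-window overlap."""
    out: dict[str, list[str]] = {}
    promo = set(promoter_peak_ids)
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for pid, iv in zip(ds.peaks.ids, ds.peaks.intervals):
        if pid in promo:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, pid))
    for _, g in ds.genes.iterrows():
        lo, hi = g["tss"] - 3000, g["tss"] + 3001
        for s, e, pid in by_chrom.get(g["chrom"], ()):
            if s < hi and lo < e:
                out.setdefault(g["gene"], []).append(pid)
    return out


def stage_comm(state: PipelineState, seed: int) -> None:
    cfg = state.config
    ds = state.dataset()
    rna, atac, peaks, ann = _analysis_cells(state)
    cdir = state.outdir / "comm"
    cdir.mkdir(exist_ok=True)

    norm = embed.lognormalize(rna.values).toarray()
    pairs = comm_mod.parse_lr_table(ds.lr_table)
    results: dict[str, pd.DataFrame] = {}
    for sex in ("XX", "XY"):
        for stg in sorted(ann["stage"].unique()):
            cond = f"{sex}_{stg}"
            m = (ann["sex"] == sex).to_numpy() & (ann["stage"] == stg).to_numpy()
            sender = m & (ann["cell_type"] == "supporting").to_numpy()
            receiver = m & (ann["cell_type"] == "PGC").to_numpy()
            if sender.sum() < 10 or receiver.sum() < 10:
                log.warning("comm: skipping %s (clusters too small)", cond)
                continue
            res = comm_mod.test_condition(
                norm, rna.feature_ids, sender, receiver, pairs,
                cfg.permutations, cfg.lr_min_frac, cfg.alpha,
                seed + 101 + sum(ord(c) for c in cond),  # stable per condition
            )
            res.insert(0, "condition", cond)
            results[cond] = res
    all_res = pd.concat(results.values(), ignore_index=True)
    pio.write_table(all_res, cdir / "interactions.tsv")
    counts, path_counts, venn = comm_mod.count_interactions(results, cfg.alpha)
    pio.write_table(counts, cdir / "counts.tsv")
    pio.write_table(path_counts, cdir / "pathway_counts.tsv")
    pio.write_table(venn, cdir / "venn.tsv")
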