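"""Synthetic 10x-multiome-style data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes for fetal mouse gonads: XX and XY cells across three embryonic
stages (E11.5/E12.5/E13.5); germ (PGC), supporting and other-somatic
populations distinguished by exclusive marker genes; Y-linked genes and
chrY peaks present only in XY cells; mitochondrial genes carrying a fixed
fraction of the library; sex-differential genes with configurable log2
effects; peak-gene pairs coupled through a shared per-cell latent activity;
TF consensus motifs planted inside the linked peaks of their targets; and
ligand-receptor pairs co-expressed between supporting cells and PGCs in a
sex-specific way.

RNA counts are gamma-Poisson (negative binomial) around population means
scaled by a log-normal cell library size; ATAC counts are Poisson. The
peak-gene coupling coefficient is solved from the moment equations of this
generative model so the planted Pearson correlation lands on the configured
strength (see docs/methods.md).

Everything planted is recorded in :class:`GroundTruth`, which downstream
tests use as the oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from . import io as pio
from .core import CountMatrix, GenomicInterval, PeakSet, ValidationError, make_gene_table

SEXES = ("XX", "XY")
STAGES = ("E11.5", "E12.5", "E13.5")
POPULATIONS = ("PGC", "supporting", "somatic")

CHRY_GENES = ("Kdm5d", "Eif2s3y", "Uty", "Ddx3y")
# Xist balances the Y-module's library share in XX cells, as in real female
# nuclei where Xist sits among the most abundant transcripts; without it the
# sex contrast would carry a compositional artifact at every gene.
XIST_GENE = "Xist"
MARKER_MEANS = {
    # gene -> (population, expected count at the reference library size,
    #          sex restriction or None)
    "Ddx4": ("PGC", 8.0, None),
    "Pou5f1": ("PGC", 8.0, None),
    "Wt1": ("supporting", 10.0, None),
    "Foxl2": ("supporting", 8.0, "XX"),
    "Runx1": ("supporting", 8.0, "XX"),
    "Sox9": ("supporting", 8.0, "XY"),
    "Tspan8": ("supporting", 6.0, None),
    "Insl3": ("somatic", 6.0, "XY"),
    "Plvap": ("somatic", 6.0, None),
    "Mafb": ("somatic", 6.0, None),
    "Pdgfra": ("somatic", 8.0, None),
    "Nr2f2": ("somatic", 8.0, None),
    "Krt19": ("somatic", 6.0, None),
    "Pecam1": ("somatic", 6.0, None),
}

LR_PATHWAYS = (
    "WNT",
    "BMP",
    "inhibin-activin",
    "ephrin",
    "nectin",
    "IGF",
    "MDK",
    "DHH",
    "Notch",
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic multiome.

    Cell numbers are per sex x stage; with the defaults the dataset holds
    2 x 3 x (170 + 170 + 160) = 3,000 singlets plus doublets.
    """

    n_pgc: int = 170
    n_supporting: int = 170
    n_somatic: int = 160
    n_genes: int = 2000
    n_peaks: int = 5000
    # RNA library size ~ lognormal(log(lib_mean), lib_sigma)
    lib_mean: float = 4000.0
    lib_sigma: float = 0.25
    nb_dispersion: float = 10.0  # gamma shape; var = mu + mu^2/theta
    # ATAC depth ~ lognormal(log(atac_mean), atac_sigma)
    atac_mean: float = 5000.0
    atac_sigma: float = 0.3
    n_chrY_genes: int = 4
    n_mito_genes: int = 13
    mito_fraction: float = 0.05
    doublet_rate: float = 0.05
    # planted sex-differential expression (within PGCs)
    n_de_genes: int = 60
    de_log2fc: float = 1.0
    # planted peak-gene links
    n_links_null: int = 20
    link_strength: float = 0.5
    # planted TF regulatory structure
    n_tfs: int = 5
    targets_per_tf: int = 8
    motif_length: int = 10
    n_cross_edges: int = 4
    # planted ligand-receptor pairs
    n_lr_xx: int = 6
    n_lr_xy: int = 4
    n_lr_shared: int = 3
    # fragments
    frags_per_cell: float = 450.0
    chrY_frag_mean: float = 8.0
    tss_frag_frac: float = 0.35
    # genome layout
    n_chrY_peaks: int = 21
    n_junk_peaks: int = 30  # nonstandard-chromosome / bad-width peaks for QC
    peak_width: int = 300
    # expression shaping
    base_count_cap: float = 20.0
    chrY_gene_counts: tuple[float, ...] = (120.0, 135.0, 150.0, 165.0)
    chrY_gene_dispersion: float = 100.0  # near-Poisson: constitutive transcripts
    n_program_genes: int = 40  # per-population expression programs
    program_multiplier: float = 3.0
    n_stage_genes: int = 30  # developmental ramp across stages in PGCs
    stage_multipliers: tuple[float, float, float] = (1.0, 1.6, 2.5)

    def __post_init__(self) -> None:
        if min(self.n_pgc, self.n_supporting, self.n_somatic) <= 0:
            raise ValidationError("population sizes must be positive")
        if not 0 <= self.doublet_rate < 1:
            raise ValidationError("doublet_rate must lie in [0, 1)")
        if not np.isfinite(self.de_log2fc):
            raise ValidationError("de_log2fc must be finite")
        n_links = self.n_de_genes + self.n_links_null
        if n_links > self.n_peaks:
            raise ValidationError(
                f"{n_links} planted links exceed {self.n_peaks} peaks"
            )
        if self.n_tfs * self.targets_per_tf > self.n_de_genes:
            raise ValidationError("more TF targets than planted DE genes")
        if not 0 < self.link_strength < 0.9:
            raise ValidationError("link_strength must lie in (0, 0.9)")


@dataclass
class GroundTruth:
    """Everything the generator planted, for use as the acceptance oracle."""

    cells: pd.DataFrame  # barcode, sex, stage, population, is_doublet
    degs: pd.DataFrame  # gene, direction, log2fc, source
    links: pd.DataFrame  # peak, gene, strength, is_de_gene
    tf_edges: pd.DataFrame  # tf, motif_id, target, peak
    motif_hits: pd.DataFrame  # peak, motif_id, offset, strand
    lr_pairs: pd.DataFrame  # pair, ligand, receptor, pathway, specificity
    dap_peaks: pd.DataFrame  # peak, direction


@dataclass
class SimulatedMultiome:
    rna: CountMatrix
    atac: CountMatrix
    peaks: PeakSet
    genes: pd.DataFrame
    fragments: pd.DataFrame
    motifs: list
    peak_sequences: dict[str, str]
    lr_table: pd.DataFrame
    truth: GroundTruth
    config: SynthConfig


# ---------------------------------------------------------------------------
# coupling calibration


def coupling_coefficient(
    target_r: float,
    mean_gene: float,
    mean_peak: float,
    nb_theta: float,
    var_lib_gene: float,
    var_lib_peak: float,
) -> float:
    """Solve for the shared-latent coefficient giving a target count-level
    Pearson correlation.

    Both the gene rate and the peak rate are multiplied by
    ``exp(a*u - a^2/2)`` with a shared standard normal ``u`` per cell. With
    independent mean-1 multiplicative factors (gamma over-dispersion for the
    gene, log-normal library factors for both), the count covariance and
    variances are available in closed form, so ``a`` is the root of a scalar
    equation.
    """
    if target_r <= 0:
        return 0.0

    def pearson(a: float) -> float:
        va = np.expm1(a * a)
        cov = mean_gene * mean_peak * va
        var_g = mean_gene + mean_gene**2 * (
            (1 + 1 / nb_theta) * (1 + va) * (1 + var_lib_gene) - 1
        )
        var_p = mean_peak + mean_peak**2 * ((1 + va) * (1 + var_lib_peak) - 1)
        return cov / np.sqrt(var_g * var_p)

    hi = 3.0
    if pearson(hi) < target_r:
        # correlation ceiling of the count model at these means
        return hi
    return brentq(lambda a: pearson(a) - target_r, 1e-9, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# doublets


def inject_doublets(
    rna: CountMatrix,
    atac: CountMatrix,
    rate: float,
    populations: pd.Series,
    seed: int,
) -> tuple[CountMatrix, CountMatrix, pd.DataFrame]:
    """Append doublet barcodes whose counts are the element-wise sum of two
    donor cells drawn from different populations (same barcode universe in
    both modalities). Returns the augmented matrices and a table of the
    doublet barcodes with their donors."""
    if not 0 <= rate < 1:
        raise ValidationError("doublet rate must lie in [0, 1)")
    n_cells = len(rna.cell_ids)
    n_doublets = int(round(rate * n_cells))
    if n_doublets == 0:
        return rna, atac, pd.DataFrame(columns=["barcode", "donor1", "donor2"])
    rng = np.random.default_rng(seed)
    pops = populations.reindex(rna.cell_ids).to_numpy()
    rows = []
    for i in range(n_doublets):
        a = int(rng.integers(n_cells))
        b = int(rng.integers(n_cells))
        while pops[b] == pops[a]:
            b = int(rng.integers(n_cells))
        rows.append((f"DBL{i:05d}", rna.cell_ids[a], rna.cell_ids[b], a, b))
    tbl = pd.DataFrame(rows, columns=["barcode", "donor1", "donor2", "_ia", "_ib"])
    ia, ib = tbl["_ia"].to_numpy(), tbl["_ib"].to_numpy()

    def augment(cm: CountMatrix) -> CountMatrix:
        extra = cm.values[:, ia] + cm.values[:, ib]
        vals = sp.hstack([cm.values, extra], format="csr")
        return CountMatrix(
            vals, cm.feature_ids, cm.cell_ids + list(tbl["barcode"]), cm.modality
        )

    return augment(rna), augment(atac), tbl[["barcode", "donor1", "donor2"]]


# ---------------------------------------------------------------------------
# main generator


def simulate_multiome(config: SynthConfig | None = None, seed: int = 0) -> SimulatedMultiome:
    cfg = config or SynthConfig()
    rng = np.random.default_rng(seed)

    genes = _build_gene_table(cfg, rng)
    gene_ids = genes["gene"].tolist()
    gi = {g: k for k, g in enumerate(gene_ids)}

    special = _assign_special_genes(cfg, genes, rng)
    mu_base = _base_expression(cfg, genes, special, rng)

    peaks, peak_roles = _build_peaks(cfg, genes, special, rng)
    link_table = _plan_links(cfg, special, peaks, peak_roles)

    # per-cell labels for singlets
    cells = _cell_table(cfg)
    n_cells = len(cells)

    rna_counts, atac_counts = _draw_counts(
        cfg, rng, genes, mu_base, special, peaks, peak_roles, link_table, cells
    )

    rna = CountMatrix(rna_counts, gene_ids, cells["barcode"].tolist(), "rna")
    atac = CountMatrix(atac_counts, peaks.ids, cells["barcode"].tolist(), "atac")

    rna, atac, doublet_tbl = inject_doublets(
        rna, atac, cfg.doublet_rate, cells.set_index("barcode")["population"], seed + 1
    )
    cells = _extend_cells_with_doublets(cells, doublet_tbl)

    motifs, peak_sequences, motif_hits, tf_edges = _plant_motifs(
        cfg, rng, special, peaks, peak_roles
    )
    gc = np.array(
        [_gc_fraction(peak_sequences[pid]) for pid in peaks.ids], dtype=float
    )
    acc = np.asarray(atac.values.mean(axis=1)).ravel()
    peaks = PeakSet(peaks.intervals, gc, acc, peaks.ids)

    fragments = _draw_fragments(cfg, rng, genes, peaks, peak_roles, cells)

    lr_table = _lr_table(special)

    degs = _deg_truth(cfg, special)
    dap = _dap_truth(special, link_table, peaks, peak_roles)

    truth = GroundTruth(
        cells=cells,
        degs=degs,
        links=link_table,
        tf_edges=tf_edges,
        motif_hits=motif_hits,
        lr_pairs=lr_table,
        dap_peaks=dap,
    )
    return SimulatedMultiome(
        rna, atac, peaks, genes, fragments, motifs, peak_sequences, lr_table, truth, cfg
    )


# ---------------------------------------------------------------------------
# gene table and expression programs


def _build_gene_table(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    special_names = (
        list(CHRY_GENES[: cfg.n_chrY_genes])
        + [XIST_GENE]
        + [f"mt-Gene{i+1}" for i in range(cfg.n_mito_genes)]
        + list(MARKER_MEANS)
        + [f"Tfx{i+1}" for i in range(cfg.n_tfs)]
    )
    lr_names = []
    n_pairs = cfg.n_lr_xx + cfg.n_lr_xy + cfg.n_lr_shared
    for i in range(n_pairs):
        lr_names.append(f"Lg{i+1:02d}")
        lr_names.append(f"Rc{i+1:02d}")
        if i < 2:  # two heteromeric receptors
            lr_names.append(f"Rc{i+1:02d}b")
    special_names += lr_names
    n_fill = cfg.n_genes - len(special_names)
    if n_fill < 200:
        raise ValidationError("n_genes too small for the planted structure")
    names = special_names + [f"Gene{i+1:04d}" for i in range(n_fill)]

    autosomes = ["chr1", "chr2", "chr3", "chr4", "chr5", "chrX"]
    chroms, starts, ends, strands = [], [], [], []
    per_chrom_cursor = {c: 100_000 for c in autosomes}
    auto_cycle = 0
    for name in names:
        if name in CHRY_GENES:
            chrom = "chrY"
            pos = 1_000_000 + CHRY_GENES.index(name) * 120_000
        elif name == XIST_GENE:
            chrom = "chrX"
            pos = 50_000_000
        elif name.startswith("mt-"):
            chrom = "chrM"
            pos = 100 + int(name[7:]) * 1_000
        else:
            chrom = autosomes[auto_cycle % len(autosomes)]
            auto_cycle += 1
            pos = per_chrom_cursor[chrom]
            per_chrom_cursor[chrom] += 60_000  # keeps TSS windows disjoint
        strand = "+" if rng.random() < 0.5 else "-"
        width = 10_000 if chrom not in ("chrM",) else 800
        chroms.append(chrom)
        starts.append(pos)
        ends.append(pos + width)
        strands.append(strand)
    return make_gene_table(names, chroms, starts, ends, strands)


def _assign_special_genes(
    cfg: SynthConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> dict:
    """Pick DE genes, null-link genes, program genes, stage genes, TF
    targets and LR partners from the gene universe, all disjoint from the
    named special genes."""
    named = set(CHRY_GENES) | set(MARKER_MEANS) | {
        g for g in genes["gene"] if g.startswith(("mt-", "Tfx", "Lg", "Rc"))
    }
    pool = [
        g
        for g, c in zip(genes["gene"], genes["chrom"])
        if g not in named and c not in ("chrY", "chrM")
    ]
    rng.shuffle(pool)
    it = iter(pool)

    def take(n: int) -> list[str]:
        return [next(it) for _ in range(n)]

    de_genes = take(cfg.n_de_genes)
    half = cfg.n_de_genes // 2
    de_dir = {g: ("XX_up" if k < half else "XY_up") for k, g in enumerate(de_genes)}
    null_link_genes = take(cfg.n_links_null)
    programs = {pop: take(cfg.n_program_genes) for pop in POPULATIONS}
    stage_genes = take(cfg.n_stage_genes)

    tfs = [f"Tfx{i+1}" for i in range(cfg.n_tfs)]
    tf_sex = {tf: ("XX" if i < (cfg.n_tfs + 1) // 2 else "XY") for i, tf in enumerate(tfs)}
    xx_up = [g for g in de_genes if de_dir[g] == "XX_up"]
    xy_up = [g for g in de_genes if de_dir[g] == "XY_up"]
    tf_targets: dict[str, list[str]] = {}
    cx, cy = 0, 0
    for tf in tfs:
        if tf_sex[tf] == "XX":
            tf_targets[tf] = xx_up[cx : cx + cfg.targets_per_tf]
            cx += cfg.targets_per_tf
        else:
            tf_targets[tf] = xy_up[cy : cy + cfg.targets_per_tf]
            cy += cfg.targets_per_tf
        if len(tf_targets[tf]) < cfg.targets_per_tf:
            raise ValidationError("not enough same-direction DE genes for TF targets")

    n_pairs = cfg.n_lr_xx + cfg.n_lr_xy + cfg.n_lr_shared
    lr = []
    for i in range(n_pairs):
        if i < cfg.n_lr_xx:
            spec = "XX"
        elif i < cfg.n_lr_xx + cfg.n_lr_xy:
            spec = "XY"
        else:
            spec = "both"
        receptor = [f"Rc{i+1:02d}"] + ([f"Rc{i+1:02d}b"] if i < 2 else [])
        lr.append(
            {
                "pair": f"LR{i+1:02d}",
                "ligand": [f"Lg{i+1:02d}"],
                "receptor": receptor,
                "pathway": LR_PATHWAYS[i % len(LR_PATHWAYS)],
                "specificity": spec,
            }
        )
    return {
        "de_genes": de_genes,
        "de_dir": de_dir,
        "null_link_genes": null_link_genes,
        "programs": programs,
        "stage_genes": stage_genes,
        "tfs": tfs,
        "tf_sex": tf_sex,
        "tf_targets": tf_targets,
        "lr": lr,
    }


def _base_expression(
    cfg: SynthConfig, genes: pd.DataFrame, special: dict, rng: np.random.Generator
) -> np.ndarray:
    """Expected counts per gene at the reference library size, before
    population/sex/stage modifiers."""
    n = len(genes)
    mu = rng.lognormal(mean=np.log(1.2), sigma=1.2, size=n)
    mu = np.minimum(mu, cfg.base_count_cap)
    gidx = {g: k for k, g in enumerate(genes["gene"])}

    # planted DE and null-link genes get moderate, well-detected expression
    for g in special["de_genes"] + special["null_link_genes"]:
        mu[gidx[g]] = rng.uniform(3.0, 6.0)
    # named genes start silent everywhere; population modifiers switch them on
    for g in list(MARKER_MEANS) + list(CHRY_GENES) + [XIST_GENE]:
        mu[gidx[g]] = 0.0
    for g in genes["gene"]:
        if g.startswith(("Tfx", "Lg", "Rc")):
            mu[gidx[g]] = 0.0
    # mitochondrial genes carry a fixed fraction of the library
    mt = genes.index[genes["is_mitochondrial"]].to_numpy()
    if len(mt):
        rest = np.delete(np.arange(n), mt)
        target = cfg.mito_fraction / (1 - cfg.mito_fraction) * mu[rest].sum()
        mu[mt] = target / len(mt)
    return mu


def _expected_counts(
    cfg: SynthConfig,
    genes: pd.DataFrame,
    mu_base: np.ndarray,
    special: dict,
    pop: str,
    sex: str,
    stage: str,
) -> np.ndarray:
    """Group-level expected counts (reference library) for one
    sex x stage x population block."""
    gidx = {g: k for k, g in enumerate(genes["gene"])}
    mu = mu_base.copy()
    up, down = 2 ** (cfg.de_log2fc / 2), 2 ** (-cfg.de_log2fc / 2)

    if sex == "XY":
        for g, c in zip(CHRY_GENES[: cfg.n_chrY_genes], cfg.chrY_gene_counts):
            mu[gidx[g]] = c
    else:
        # Xist matches the Y-module's library share so the two sexes have
        # no global compositional offset
        mu[gidx[XIST_GENE]] = float(sum(cfg.chrY_gene_counts[: cfg.n_chrY_genes]))
    for g, (mpop, count, msex) in MARKER_MEANS.items():
        if pop == mpop and (msex is None or msex == sex):
            mu[gidx[g]] = count
    # program/stage boosts are capped below the chrY gene abundances so the
    # Y-linked module stays the top-ranked signature in XY cells
    for g in special["programs"][pop]:
        mu[gidx[g]] = min(mu[gidx[g]] * cfg.program_multiplier, cfg.base_count_cap)
    if pop == "PGC":
        smult = cfg.stage_multipliers[STAGES.index(stage)]
        for g in special["stage_genes"]:
            mu[gidx[g]] = min(mu[gidx[g]] * smult, cfg.base_count_cap)
        for g in special["de_genes"]:
            fav = special["de_dir"][g] == f"{sex}_up"
            mu[gidx[g]] *= up if fav else down
        for tf in special["tfs"]:
            mu[gidx[tf]] = 6.0 * (up if special["tf_sex"][tf] == sex else down)
    else:
        for tf in special["tfs"]:
            mu[gidx[tf]] = 0.3  # germline-enriched TFs leak weakly into soma
    for rec in special["lr"]:
        active = rec["specificity"] in (sex, "both")
        if pop == "supporting":
            for g in rec["ligand"]:
                mu[gidx[g]] = 6.0 if active else 0.0
        if pop == "PGC":
            for g in rec["receptor"]:
                mu[gidx[g]] = 6.0 if active else 0.0
    return mu


# ---------------------------------------------------------------------------
# peaks


def _build_peaks(
    cfg: SynthConfig, genes: pd.DataFrame, special: dict, rng: np.random.Generator
) -> tuple[PeakSet, dict]:
    """Lay out promoter peaks, linked distal peaks, chrY peaks, junk peaks
    and random intergenic peaks. Returns the PeakSet (GC/accessibility
    filled later) and a role map."""
    half = cfg.peak_width // 2
    intervals: list[GenomicInterval] = []
    roles: dict = {"promoter_of": {}, "linked": {}, "chrY": [], "junk": []}

    link_genes = special["de_genes"] + special["null_link_genes"]
    promoter_genes = set(
        list(MARKER_MEANS)
        + special["tfs"]
        + link_genes
        + [g for g in genes["gene"] if g.startswith(("Lg", "Rc"))]
    )
    by_gene = genes.set_index("gene")
    extra = [
        g
        for g in genes["gene"]
        if g not in promoter_genes and by_gene.loc[g, "chrom"] not in ("chrY", "chrM")
    ]
    n_promoters = min(1200, len(promoter_genes) + len(extra))
    promo_list = sorted(promoter_genes) + extra
    promo_list = promo_list[:n_promoters]

    for g in promo_list:
        tss = int(by_gene.loc[g, "tss"])
        iv = GenomicInterval(by_gene.loc[g, "chrom"], max(0, tss - half), tss + half)
        roles["promoter_of"][len(intervals)] = g
        intervals.append(iv)

    for g in link_genes:
        tss = int(by_gene.loc[g, "tss"])
        offset = int(rng.integers(20_000, 100_000)) * (1 if rng.random() < 0.5 else -1)
        center = max(half + 1, tss + offset)
        iv = GenomicInterval(by_gene.loc[g, "chrom"], center - half, center + half)
        roles["linked"][len(intervals)] = g
        intervals.append(iv)

    for i in range(cfg.n_chrY_peaks):
        start = int(rng.integers(1_000_000, 89_000_000))
        roles["chrY"].append(len(intervals))
        intervals.append(GenomicInterval("chrY", start, start + cfg.peak_width))

    # junk peaks the QC stage should remove: nonstandard chromosomes and
    # out-of-range widths
    n_junk = cfg.n_junk_peaks
    for i in range(n_junk):
        if i % 3 == 0:
            iv = GenomicInterval("chrUn_random", 1000 + i * 5000, 1300 + i * 5000)
        elif i % 3 == 1:
            s = 5000 + i * 4000
            iv = GenomicInterval("chr1", s, s + 15)  # too narrow
        else:
            s = 2_000_000 + i * 40_000
            iv = GenomicInterval("chr2", s, s + 12_000)  # too wide
        roles["junk"].append(len(intervals))
        intervals.append(iv)

    chroms = ["chr1", "chr2", "chr3", "chr4", "chr5", "chrX"]
    seen = {(iv.chrom, iv.start, iv.end) for iv in intervals}
    while len(intervals) < cfg.n_peaks:
        c = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(50_000, 25_000_000))
        width = int(rng.integers(150, 800))
        key = (c, start, start + width)
        if key in seen:
            continue
        seen.add(key)
        intervals.append(GenomicInterval(c, start, start + width))
    return PeakSet(intervals), roles


def _plan_links(
    cfg: SynthConfig, special: dict, peaks: PeakSet, roles: dict
) -> pd.DataFrame:
    rows = []
    de_set = set(special["de_genes"])
    for pidx, g in roles["linked"].items():
        rows.append(
            {
                "peak": peaks.ids[pidx],
                "gene": g,
                "strength": cfg.link_strength,
                "is_de_gene": g in de_set,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# count drawing


def _cell_table(cfg: SynthConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for sex in SEXES:
        for stage in STAGES:
            for pop, npop in zip(
                POPULATIONS, (cfg.n_pgc, cfg.n_supporting, cfg.n_somatic)
            ):
                for _ in range(npop):
                    rows.append((f"CELL{i:06d}", sex, stage, pop, False))
                    i += 1
    return pd.DataFrame(
        rows, columns=["barcode", "sex", "stage", "population", "is_doublet"]
    )


def _extend_cells_with_doublets(
    cells: pd.DataFrame, doublet_tbl: pd.DataFrame
) -> pd.DataFrame:
    if len(doublet_tbl) == 0:
        return cells
    by_bc = cells.set_index("barcode")
    rows = []
    for _, r in doublet_tbl.iterrows():
        d1 = by_bc.loc[r["donor1"]]
        rows.append(
            (r["barcode"], d1["sex"], d1["stage"], "doublet", True)
        )
    extra = pd.DataFrame(
        rows, columns=["barcode", "sex", "stage", "population", "is_doublet"]
    )
    return pd.concat([cells, extra], ignore_index=True)


def _draw_counts(
    cfg: SynthConfig,
    rng: np.random.Generator,
    genes: pd.DataFrame,
    mu_base: np.ndarray,
    special: dict,
    peaks: PeakSet,
    roles: dict,
    link_table: pd.DataFrame,
    cells: pd.DataFrame,
) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    n_genes, n_peaks = len(genes), len(peaks)
    gidx = {g: k for k, g in enumerate(genes["gene"])}
    theta = cfg.nb_dispersion
    # per-gene dispersion: Y-linked module genes are near-Poisson so their
    # per-cell rank among top transcripts stays stable
    theta_g = np.full(n_genes, theta)
    for g in list(CHRY_GENES[: cfg.n_chrY_genes]) + [XIST_GENE]:
        theta_g[gidx[g]] = cfg.chrY_gene_dispersion
    v_lib_g = float(np.expm1(cfg.lib_sigma**2))
    v_lib_p = float(np.expm1(cfg.atac_sigma**2))

    # per-peak base accessibility weights (expected counts at reference depth)
    peak_mu = rng.lognormal(mean=np.log(0.7), sigma=1.0, size=n_peaks)
    peak_mu = np.minimum(peak_mu, 12.0)
    linked_idx = np.array(sorted(roles["linked"]), dtype=int)
    peak_mu[linked_idx] = rng.uniform(2.5, 4.5, size=len(linked_idx))
    chry_idx = np.array(roles["chrY"], dtype=int)
    peak_mu[chry_idx] = 2.0
    junk_idx = np.array(roles["junk"], dtype=int)
    peak_mu[junk_idx] = 0.3

    # coupling coefficients per link, from the moment equations; means are
    # the post-normalization expected counts (library scale / total weight)
    link_gene_idx = np.array([gidx[roles["linked"][i]] for i in linked_idx])
    rna_weight_sum = mu_base.sum() + float(
        sum(cfg.chrY_gene_counts[: cfg.n_chrY_genes])
    )
    g_scale = cfg.lib_mean / max(rna_weight_sum, 1e-9)
    p_scale = cfg.atac_mean / max(peak_mu.sum(), 1e-9)
    coeffs = np.array(
        [
            coupling_coefficient(
                row_strength,
                max(mu_base[gk] * g_scale, 0.5),
                peak_mu[pk] * p_scale,
                theta,
                v_lib_g,
                v_lib_p,
            )
            for row_strength, gk, pk in zip(
                link_table.set_index("peak")
                .loc[[peaks.ids[i] for i in linked_idx], "strength"]
                .to_numpy(),
                link_gene_idx,
                linked_idx,
            )
        ]
    )

    up, down = 2 ** (cfg.de_log2fc / 2), 2 ** (-cfg.de_log2fc / 2)
    de_dir = special["de_dir"]
    linked_gene_names = [roles["linked"][i] for i in linked_idx]

    rna_blocks, atac_blocks = [], []
    for (sex, stage, pop), grp in cells.groupby(
        ["sex", "stage", "population"], sort=False
    ):
        nc = len(grp)
        mu = _expected_counts(cfg, genes, mu_base, special, pop, sex, stage)
        lib = rng.lognormal(np.log(cfg.lib_mean), cfg.lib_sigma, size=nc)
        depth = rng.lognormal(np.log(cfg.atac_mean), cfg.atac_sigma, size=nc)

        # shared latent per link per cell couples gene and peak rates
        u = rng.standard_normal((len(linked_idx), nc))
        latent = np.exp(coeffs[:, None] * u - (coeffs**2)[:, None] / 2)

        rate_rna = np.outer(mu, lib / max(mu.sum(), 1e-9))
        rate_rna[link_gene_idx, :] *= latent
        gamma = rng.gamma(theta_g[:, None], 1.0 / theta_g[:, None], size=(n_genes, nc))
        rna_counts = rng.poisson(rate_rna * gamma)

        pmu = peak_mu.copy()
        if sex == "XX":
            pmu[chry_idx] = 0.0
        sex_mult = np.ones(len(linked_idx))
        for j, g in enumerate(linked_gene_names):
            if g in de_dir:
                sex_mult[j] = up if de_dir[g] == f"{sex}_up" else down
        rate_atac = np.outer(pmu, depth / max(pmu.sum(), 1e-9))
        rate_atac[linked_idx, :] *= latent * sex_mult[:, None]
        atac_counts = rng.poisson(rate_atac)

        rna_blocks.append(sp.csr_matrix(rna_counts))
        atac_blocks.append(sp.csr_matrix(atac_counts))

    return (
        sp.hstack(rna_blocks, format="csr"),
        sp.hstack(atac_blocks, format="csr"),
    )


# ---------------------------------------------------------------------------
# motifs and sequences

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def _plant_motifs(
    cfg: SynthConfig,
    rng: np.random.Generator,
    special: dict,
    peaks: PeakSet,
    roles: dict,
) -> tuple[list, dict, pd.DataFrame, pd.DataFrame]:
    # one sharply informative consensus PFM per TF
    motifs = []
    consensi = {}
    for i, tf in enumerate(special["tfs"]):
        while True:
            cons = "".join(
                "ACGT"[k] for k in rng.integers(0, 4, size=cfg.motif_length)
            )
            if cons not in consensi.values():
                break
        consensi[tf] = cons
        pfm = np.ones((4, cfg.motif_length))
        for j, b in enumerate(cons):
            pfm["ACGT".index(b), j] = 20.0
        motifs.append({"id": f"MA{i+1:04d}", "name": tf, "pfm": pfm})
    motif_id = {tf: m["id"] for tf, m in zip(special["tfs"], motifs)}

    # random peak backgrounds with a peak-specific GC level
    seqs: dict[str, str] = {}
    gc_level = np.clip(rng.beta(10, 12, size=len(peaks)), 0.25, 0.65)
    for pid, iv, gc in zip(peaks.ids, peaks.intervals, gc_level):
        L = iv.width
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        seqs[pid] = (
            rng.choice(BASES, size=L, p=p).tobytes().decode("ascii")
        )

    link_peak_of = {
        g: peaks.ids[i] for i, g in roles["linked"].items()
    }
    promoter_peak_of = {g: peaks.ids[i] for i, g in roles["promoter_of"].items()}

    hit_rows, edge_rows = [], []

    def plant(peak_id: str, tf: str) -> int:
        seq = seqs[peak_id]
        cons = consensi[tf]
        offset = int(rng.integers(0, max(1, len(seq) - len(cons))))
        seqs[peak_id] = seq[:offset] + cons + seq[offset + len(cons) :]
        hit_rows.append(
            {"peak": peak_id, "motif_id": motif_id[tf], "offset": offset, "strand": "+"}
        )
        return offset

    for tf, targets in special["tf_targets"].items():
        for g in targets:
            pk = link_peak_of[g]
            plant(pk, tf)
            edge_rows.append(
                {"tf": tf, "motif_id": motif_id[tf], "target": g, "peak": pk}
            )

    # cross-regulation: earlier TFs' motifs in later TFs' promoter peaks
    tfs = special["tfs"]
    for k in range(min(cfg.n_cross_edges, len(tfs) * (len(tfs) - 1))):
        a = tfs[k % len(tfs)]
        b = tfs[(k + 1) % len(tfs)]
        pk = promoter_peak_of.get(b)
        if pk is not None:
            plant(pk, a)

    return (
        motifs,
        seqs,
        pd.DataFrame(hit_rows),
        pd.DataFrame(edge_rows),
    )


# ---------------------------------------------------------------------------
# fragments


def _draw_fragments(
    cfg: SynthConfig,
    rng: np.random.Generator,
    genes: pd.DataFrame,
    peaks: PeakSet,
    roles: dict,
    cells: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cell ATAC fragments: a bimodal length mixture (sub-nucleosomal
    ~80 bp, mono-nucleosomal ~195 bp), a TSS-centred pileup, uniform
    background on autosomes/chrX, and chrY-peak fragments for XY barcodes
    only."""
    tss_pool = genes.loc[
        ~genes["chrom"].isin(["chrY", "chrM"]), ["chrom", "tss"]
    ].reset_index(drop=True)
    chrom_sizes = {
        "chr1": 30_000_000,
        "chr2": 30_000_000,
        "chr3": 30_000_000,
        "chr4": 30_000_000,
        "chr5": 30_000_000,
        "chrX": 30_000_000,
    }
    chrom_names = list(chrom_sizes)
    chry = [peaks.intervals[i] for i in roles["chrY"]]

    out_chrom, out_start, out_end, out_bc, out_cnt = [], [], [], [], []

    def lengths(n: int) -> np.ndarray:
        mono = rng.random(n) < 0.38
        ln = np.where(
            mono,
            rng.normal(195, 25, size=n),
            rng.normal(80, 15, size=n),
        )
        return np.clip(np.rint(ln), 25, 600).astype(int)

    for _, cell in cells.iterrows():
        n = rng.poisson(cfg.frags_per_cell)
        if n == 0:
            continue
        n_tss = rng.binomial(n, cfg.tss_frag_frac)
        n_bg = n - n_tss
        ls = lengths(n)
        # TSS-centred fragments
        if n_tss:
            pick = rng.integers(0, len(tss_pool), size=n_tss)
            centers = tss_pool["tss"].to_numpy()[pick] + np.rint(
                rng.normal(0, 70, size=n_tss)
            ).astype(int)
            starts = np.maximum(1, centers - ls[:n_tss] // 2)
            out_chrom.extend(tss_pool["chrom"].to_numpy()[pick])
            out_start.extend(starts)
            out_end.extend(starts + ls[:n_tss])
            out_bc.extend([cell["barcode"]] * n_tss)
        # uniform background
        if n_bg:
            ci = rng.integers(0, len(chrom_names), size=n_bg)
            pos = rng.integers(1, 29_000_000, size=n_bg)
            out_chrom.extend(np.array(chrom_names)[ci])
            out_start.extend(pos)
            out_end.extend(pos + ls[n_tss:])
            out_bc.extend([cell["barcode"]] * n_bg)
        # chrY-peak fragments, XY cells only
        if cell["sex"] == "XY" and chry:
            ny = rng.poisson(cfg.chrY_frag_mean)
            for _ in range(ny):
                iv = chry[int(rng.integers(len(chry)))]
                ln = int(lengths(1)[0])
                s = int(rng.integers(iv.start, max(iv.start + 1, iv.end - 10)))
                out_chrom.append(iv.chrom)
                out_start.append(s)
                out_end.append(s + ln)
                out_bc.append(cell["barcode"])

    df = pd.DataFrame(
        {
            "chrom": out_chrom,
            "start": np.asarray(out_start, dtype=np.int64),
            "end": np.asarray(out_end, dtype=np.int64),
            "barcode": out_bc,
        }
    )
    df["count"] = np.where(rng.random(len(df)) < 0.05, 2, 1)
    df = df.sort_values(
        ["chrom", "start", "end", "barcode"], kind="mergesort"
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# ground-truth tables


def _lr_table(special: dict) -> pd.DataFrame:
    rows = []
    for rec in special["lr"]:
        rows.append(
            {
                "pair": rec["pair"],
                "ligand": ",".join(rec["ligand"]),
                "receptor": ",".join(rec["receptor"]),
                "pathway": rec["pathway"],
                "specificity": rec["specificity"],
            }
        )
    return pd.DataFrame(rows)


def _deg_truth(cfg: SynthConfig, special: dict) -> pd.DataFrame:
    rows = []
    for g in special["de_genes"]:
        rows.append(
            {
                "gene": g,
                "direction": special["de_dir"][g],
                "log2fc": cfg.de_log2fc,
                "source": "planted",
            }
        )
    for tf in special["tfs"]:
        rows.append(
            {
                "gene": tf,
                "direction": f"{special['tf_sex'][tf]}_up",
                "log2fc": cfg.de_log2fc,
                "source": "tf",
            }
        )
    for rec in special["lr"]:
        if rec["specificity"] in ("XX", "XY"):
            for g in rec["receptor"]:
                rows.append(
                    {
                        "gene": g,
                        "direction": f"{rec['specificity']}_up",
                        "log2fc": np.inf,
                        "source": "lr_receptor",
                    }
                )
    for g in CHRY_GENES[: cfg.n_chrY_genes]:
        rows.append(
            {"gene": g, "direction": "XY_up", "log2fc": np.inf, "source": "chrY"}
        )
    rows.append(
        {"gene": XIST_GENE, "direction": "XX_up", "log2fc": np.inf, "source": "xist"}
    )
    return pd.DataFrame(rows)


def _dap_truth(
    special: dict, links: pd.DataFrame, peaks: PeakSet, roles: dict
) -> pd.DataFrame:
    rows = []
    de_dir = special["de_dir"]
    for _, r in links.iterrows():
        if r["is_de_gene"]:
            rows.append({"peak": r["peak"], "direction": de_dir[r["gene"]]})
    for i in roles["chrY"]:
        rows.append({"peak": peaks.ids[i], "direction": "XY_up"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset serialization


def write_dataset(ds: SimulatedMultiome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pio.write_count_matrix(ds.rna, outdir, prefix="rna_")
    pio.write_count_matrix(ds.atac, outdir, prefix="atac_")
    pio.write_peaks_bed(ds.peaks, outdir / "peaks.bed")
    pio.write_table(ds.genes, outdir / "genes.tsv")
    pio.write_fragments(ds.fragments, outdir / "fragments.tsv")
    pio.write_jaspar_pfm(ds.motifs, outdir / "motifs.jaspar")
    pio.write_fasta(ds.peak_sequences, outdir / "peak_sequences.fa")
    pio.write_table(ds.lr_table, outdir / "lr_pairs.tsv")
    # sample-of-origin metadata (sex and stage of each library) is observed
    # in a real experiment, so it ships with the dataset, not the truth
    pio.write_table(
        ds.truth.cells[["barcode", "sex", "stage"]], outdir / "samples.tsv"
    )
    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    for name in ("cells", "degs", "links", "tf_edges", "motif_hits", "lr_pairs", "dap_peaks"):
        pio.write_table(getattr(ds.truth, name), truth_dir / f"{name}.tsv")


def load_dataset(outdir: str | Path) -> SimulatedMultiome:
    outdir = Path(outdir)
    rna = pio.read_count_matrix(
        outdir / "rna_matrix.mtx", outdir / "rna_features.tsv", outdir / "rna_barcodes.tsv", "rna"
    )
    atac = pio.read_count_matrix(
        outdir / "atac_matrix.mtx", outdir / "atac_features.tsv", outdir / "atac_barcodes.tsv", "atac"
    )
    peaks = pio.read_peaks_bed(outdir / "peaks.bed")
    peaks = PeakSet(peaks.intervals, peaks.gc_content, peaks.mean_accessibility, atac.feature_ids)
    genes = pio.read_gene_table(outdir / "genes.tsv")
    fragments = pio.read_fragments_frame(outdir / "fragments.tsv")
    motifs = pio.read_jaspar_pfm(outdir / "motifs.jaspar")
    seqs = pio.read_fasta(outdir / "peak_sequences.fa")
    lr = pd.read_csv(outdir / "lr_pairs.tsv", sep="\t")
    tdir = outdir / "ground_truth"
    truth = GroundTruth(
        cells=pd.read_csv(tdir / "cells.tsv", sep="\t"),
        degs=pd.read_csv(tdir / "degs.tsv", sep="\t"),
        links=pd.read_csv(tdir / "links.tsv", sep="\t"),
        tf_edges=pd.read_csv(tdir / "tf_edges.tsv", sep="\t"),
        motif_hits=pd.read_csv(tdir / "motif_hits.tsv", sep="\t"),
        lr_pairs=pd.read_csv(tdir / "lr_pairs.tsv", sep="\t"),
        dap_peaks=pd.read_csv(tdir / "dap_peaks.tsv", sep="\t"),
    )
    return SimulatedMultiome(
        rna, atac, peaks, genes, fragments, motifs, seqs, lr, truth, SynthConfig()
    )
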