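# pgcmultiome

Analysis pipeline for paired single-nucleus RNA + ATAC (10x-multiome-style)
data from fetal mouse gonads, built around the question of how primordial
germ cells (PGCs) commit to the oogonial or spermatogonial fate. The package
implements the complete downstream workflow — cell QC and marker-count
triage, chromosomal-sex confirmation, multimodal reduction/clustering and
MST pseudotime, Wilcoxon differential expression and accessibility,
peak-to-gene linkage against GC-matched backgrounds, motif scanning,
enrichment and per-cell motif activity, TF-candidate triage into a gene
regulatory network, and a permutation ligand-receptor test — and ships a
synthetic multiome generator with planted ground truth that serves as the
oracle for every stage.

## The statistics at the core

**Peak-to-gene linkage.** For a peak *p* and gene *g* within 500 kb,
*r* = Pearson(accessibility_p, expression_g) across cells. The null draws
*n* = 200 background peaks matched to *p* on GC-content and accessibility
deciles, giving *z* = (*r* − mean *r*₀)/sd *r*₀ and a one-sided
*p* = 1 − Φ(*z*); links are retained when *p* < 0.05 and *z* > 0.

**Motif activity (deviation z-score).** With *e_p* the fraction of all
counts in peak *p*, the expected motif count for cell *i* is
*x* = *T_i* · Σ_{p∈motif} *e_p*; the raw deviation is (*o* − *x*)/*x* and is
standardized against 50 iterations in which each motif peak is replaced by
a GC/accessibility-matched peak.

**Rank module score.** Per cell, genes are ranked by descending expression
with ranks clipped at 1500; with *U* = Σ rank(signature) − *n*(*n*+1)/2 the
score is 1 − *U*/(*n*·(1500 − *n*)), in [0, 1]. The Y-linked module
(*Kdm5d, Eif2s3y, Uty, Ddx3y*) plus chrY-peak fragment counts drive the
sex calls.

**Differential testing.** Wilcoxon rank-sum (exact enumeration for small
groups, tie-corrected normal approximation otherwise) on ln-CP10K values,
pre-filtered at min.pct/log2FC (0.25/0.25 for genes, 0.001/0.1 for peaks),
with Bonferroni adjustment over all features.

**Ligand-receptor test.** Statistic = (ligand complex mean in sender +
receptor complex mean in receiver)/2, where a heteromeric complex scores
as its least-expressed subunit and is gated to zero below 10% detection;
*p* = (1 + #{null ≥ obs})/(1 + 1000) over label permutations.

## Worked example

```bash
pgcmultiome all --data-dir data/ --outdir out/ --seed 1
```

or from Python (`examples/05_full_pipeline_and_grn.py`):

```text
TF triage (sex-DE, germline-enriched, motif-enriched, activity z > 0):
  tf  is_de_between_sexes  is_germline_enriched  motif_enriched  mean_motif_activity_z  passes_all
Tfx3                 True                  True            True                1.46086        True
Tfx1                 True                  True            True                1.23410        True
...
significant ligand-receptor interactions (XX-only / XY-only / shared):
stage  xx_only  xy_only  shared
E13.5        6        4       3
```

Every planted TF passes all four triage criteria, and the sex partition of
significant signaling pairs (6 XX-only, 4 XY-only, 3 shared) matches what
the generator planted. The `out/` directory holds one TSV table set per
stage (qc, sex, cluster, de, link, motif, grn, comm).

The `examples/` directory has one short script per capability: simulation,
QC/triage, sexing, DE + linkage, and the full pipeline.

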