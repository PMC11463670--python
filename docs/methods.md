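# Methods

## Scope and data model

The package analyses paired gene×cell RNA counts and peak×cell ATAC counts
with a per-cell fragment file, gene models, peak intervals with GC
content, JASPAR-format motifs and a ligand-receptor table. All genomic
coordinates are 0-based half-open everywhere (BED-native); any 1-based
dialect must be converted at the boundary. Counts are sparse non-negative
integers; both modalities share one barcode universe.

## Synthetic multiome generator

The generator is first-class, tested code: it defines the study conditions
every acceptance measurement runs under.

**Populations and design.** Two sexes (XX, XY) × three stages (E11.5,
E12.5, E13.5) × three populations — PGC (170/condition), supporting (170),
other-somatic (160) — give 3,000 singlets; 5% doublets are appended as
element-wise sums of two donors from different populations of the same
sample. 2,000 genes and 5,000 peaks sit on a six-chromosome synthetic
genome plus chrY (90 Mb region, 21 peaks) and chrM (13 genes carrying ~5%
of the library).

**Counts.** RNA is gamma-Poisson: rate = library × normalized gene weight ×
modifiers, with gene-level dispersion θ = 10 (variance = μ + μ²/θ) and
library size ~ lognormal(ln 4000, 0.25). ATAC is Poisson at depth ~
lognormal(ln 5000, 0.3). Ordinary gene weights are lognormal capped at 20
expected counts.

**Sex signal.** The four Y-linked genes are planted at 120–165 expected
counts with near-Poisson dispersion (θ = 100), making them the top-ranked
transcripts of essentially every XY nucleus, so the rank module score is
exactly 1 for XY and exactly 0 for XX cells. An Xist analogue of equal
total abundance is planted in XX cells — as in real female nuclei, where
Xist is among the most abundant transcripts — so the two sexes have no
global compositional offset after CP10K normalization. This separation is
deliberately cleaner than real tissue: passing the sexing tests shows the
thresholding rules are implemented correctly, not that real data separates
this sharply. chrY fragments (mean 8 per XY cell) appear only in XY
barcodes; XX singlets have zero by construction.

**Markers and programs.** Each population expresses an exclusive marker
panel (Ddx4/Pou5f1 for PGCs; Wt1 plus sex-appropriate Foxl2/Runx1 or Sox9
for supporting cells; Pdgfra/Nr2f2/Plvap/… for other somatic cells) at 6–10
expected counts and zero elsewhere — the count-based triage rules assume
exactly this exclusivity. Forty program genes per population (×3, capped
at 20) give the clustering real structure; thirty stage-ramp genes
(×1/1.6/2.5) give pseudotime a direction.

**Differential structure.** Sixty genes are sex-differential within PGCs
at |log2FC| = 1 (multiplicative ±2^0.5), half up in each sex; the five TF
genes (mean 6 in PGCs, 0.3 in soma — germline-enriched) carry the same sex
effect, as do the sex-specific ligand/receptor genes. The linked peak of
each DE gene inherits the gene's sex multiplier, making it differentially
accessible.

**Peak–gene coupling.** Each of the 80 planted links (60 on DE genes, 20
on neutral genes) shares a standard-normal latent *u* per cell: both rates
are multiplied by exp(*a·u* − *a*²/2). Because every factor is an
independent mean-1 multiplier, count covariance and variances are
closed-form, and *a* is solved by Brent's method so the count-level
Pearson r equals the configured strength (0.5 by default) — verified
empirically to ±0.05 at 500 cells. Means entering the solver are the
post-normalization expected counts.

**Motifs and sequences.** Each TF gets a length-10 consensus PFM
(count 20 vs 1), sharp enough that only exact consensus matches reach the
0.8·max-score scanning threshold; the consensus is spliced into the linked
peak of each of its 8 targets at a recorded offset, and into a few other
TFs' promoter peaks for cross-regulation. Peak sequences are random with
Beta-distributed GC, and per-peak GC is computed from the actual sequence,
so scanner and generator agree exactly without a genome FASTA.

**Fragments.** ~450 per cell: 35% TSS-centred (σ = 70 bp) giving TSS
enrichment ≫ 1, the rest uniform; lengths are a sub-nucleosomal
(~80 ± 15 bp, 62%) / mono-nucleosomal (~195 ± 25 bp) mixture giving a
nucleosome signal ≈ 0.6. 5% of fragments carry duplicate count 2.

**What the generator does not model.** Ambient RNA, batch effects,
read-level errors, realistic motif co-occurrence, chromatin domains, and
RNA/ATAC depth correlation. Tests passing on this generator certify the
statistical machinery, not performance on real tissue.

## Analysis stages

**QC.** nCount_RNA ∈ (1000, 25000), pct_mito < 25, nCount_ATAC ∈
(1000, 100000), nucleosome signal < 2, TSS enrichment > 1 — all strict,
matching the printed operators. Nucleosome signal = mono-nucleosomal
(147–294 bp)/sub-nucleosomal (<147 bp) fragment ratio; TSS enrichment =
per-bp coverage in TSS±250 over the mean of flanks [−2000,−1900) and
(1900,2000], with 0/0 → 0 and finite/0 → 1e6 sentinel. These definitions
follow the cited QC tooling, stated here so the numbers are reproducible.
Peaks keep width ∈ (20, 10000), standard chromosomes, no blacklist
overlap. The triage labels PGC iff any germ marker ≥ 1 count ("OR" across
Ddx4/Pou5f1, configurable to "AND") and all eleven somatic exclusion
markers = 0; supporting iff Wt1 ≥ 2 and six exclusion markers = 0;
"count < 1" is read as exactly 0 and "count > 1" as ≥ 2 on raw integers.
Mitochondrial genes are dropped after the pct_mito computation.

**Sexing.** The rank module score (UCell-style Mann-Whitney form, ceiling
1500) of the Y-linked module, plus duplicate-weighted fragment counts in
chrY peaks within 1–90 Mb. Reference cuts come from E13.5 cells:
male_cut = mean − 1 sd of XY-reference scores, female_cut = mean + 1 sd of
XX-reference scores. A claimed-male cell is demoted to ambiguous when
chrY fragments = 0 or score < male_cut; a claimed-female cell when chrY
fragments > 1 or score > female_cut. The source wording ("above/below one
standard deviation of the mean") is ambiguous about direction; this
mirror reading is the only one under which a homogeneous reference
population retains its own members, and both cut directions are
configurable (`sd_factor`, and the caller chooses the references).

**Reduction and clustering.** RNA: ln-CP10K, 2,000 top-variance genes,
per-gene scaling clipped at ±10, full-SVD PCA, components 1–18 downstream.
(A variance-stabilizing regression normalization would be the field's
default; ln-CP10K is deterministic, dependency-free, and sufficient for
these contracts — a documented divergence.) ATAC: TF-IDF
(ln(1 + TF·IDF·1e4)) then truncated SVD; component 1 is flagged when
|r| with log depth > 0.7 and defaults use components 2–30. Clustering:
kNN (k = 20) → SNN Jaccard graph → RB-configuration modularity at
resolution 0.3 via a seeded Leiden optimizer (one optimizer for both
modalities), labels ordered by cluster size. Weighted joint neighbors use
a within- vs cross-modality prediction contrast per cell — not the full
published WNN kernel; the contract tested is qualitative (an uninformative
modality is down-weighted below 0.3 median). Pseudotime is an MST over
cluster centroids in the blended joint space, rooted at the cluster
holding the most E11.5 PGCs; cells project onto their incoming edge;
branch points are degree-≥3 nodes and terminals are non-root leaves. This
replaces principal-graph learning; the trajectory contract tested is
topological (a planted Y gives one branch and two terminals), not
coordinate-level.

**Differential.** Wilcoxon rank-sum with exact enumeration when
min(n₁,n₂) ≤ 8 and C(n₁+n₂, min) ≤ 2·10⁵ (ties handled exactly by
enumerating rank assignments), else the tie- and continuity-corrected
normal approximation. Fold change = log2((mean₁+1)/(mean₂+1)) on de-logged
normalized means; pct = fraction of cells with count > 0. Adjustment
defaults to Bonferroni over all features (the marker-finding convention;
BH over the tested subset is available but does not control the empirical
FDR after the fold-change pre-filter, which selects noise-inflated
features). DAP thresholds default to min.pct 0.001 / log2FC 0.1 (the
Methods values; the stricter 0.25 figure-caption variant is a config
change). Peak annotation: promoter (TSS±3000, strand-aware) > exon >
intron > distal, half-open overlap. Gene-set over-representation is an
upper-tail hypergeometric with BH; gene sets are user-supplied.

**Linkage.** Candidate pairs are peak-midpoint to TSS ≤ 500 kb on the same
chromosome. Links are computed **within each sex's PGCs**: pooling sexes
lets sex-differential abundance masquerade as coupling (every DA peak
correlates with every DEG), collapsing network precision; downstream
stages use the union of the per-sex retained links. Backgrounds are 200
peaks from the focal peak's (GC decile × accessibility decile) stratum,
widening ring-by-ring when short; ties share a bin so degenerate features
match cleanly. One-sided upper-tail p, retained at p < 0.05 and z > 0.

**Motifs.** Log-odds PWMs with pseudocount 0.8 split by background base
frequencies; scanning reports all windows on both strands at ≥ 0.8 of the
motif's maximum score (a deterministic threshold in place of a p-value
one; configurable). Enrichment foreground = E13.5 DA peaks linked to E13.5
DEGs, background = 2,000 matched peaks, upper-tail hypergeometric with BH.
Deviations use 50 matched-resampling iterations; per-population means are
reported per cell-type × sex group.

**GRN.** A TF passes triage iff (a) sex-DE at the focal stage (adjusted
p < 0.05, |log2FC| ≥ 0.25), (b) germline-enriched (positive DE in PGCs vs
pooled soma), (c) motif enriched in DA-linked-peaks (p < 0.05), and
(d) mean deviation z > 0 in PGCs of its favored sex. Criterion (c) uses DA
peaks linked to DEGs (the stricter of the two readings the source allows;
configurable). Edges connect a passing TF to a DEG when a retained link's
peak carries its motif; duplicates keep the best-p peak. Coverage =
targets / DEGs-with-links. Cross-regulation marks motif presence in a
TF's retained linked peaks or promoter peaks (TSS±3000).

**Cell communication.** Per sex × stage, sender = supporting cells,
receiver = PGCs (each ≥ 10 cells). Minimum-subunit complex rule, 10%
detection gate, 1,000 label permutations with +1 smoothing (the cited
method's published defaults; the source names only the method). Outputs
include per-condition counts, per-pathway counts, and the XX-only /
XY-only / shared partition per stage. The bundled ligand-receptor table is
synthetic: it mirrors the pathway labels (WNT, BMP, inhibin-activin,
ephrin, nectin, IGF, MDK, DHH, Notch) without claiming any real database's
content.

## Numerical and design choices

- Determinism: every stochastic step draws from `numpy.random.default_rng`
  with a seed derived from the pipeline seed; tables are written with a
  fixed float format; identical (inputs, config, seed) give byte-identical
  outputs.
- PCA/SVD sign convention: the largest-magnitude loading is positive.
- Degenerate inputs: all-zero cells normalize to zero; zero-variance peaks
  or genes are skipped from linkage with a recorded reason; motifs with
  zero expected counts get NaN deviations; an empty post-filter DE table
  is returned, not raised.
- Problem sizes in the test suite (small generator configs, 20 linkage
  replicates at ~500 cells, 200-pair null batteries) are chosen so each
  statistical property is measured at the size where its stated bound has
  comfortable margin.

## Known limitations

Library-size normalization induces weak cross-feature dependence, so
null false-positive fractions fluctuate slightly more than binomial
sampling alone would suggest. The WNN weights and pseudotime are
simplified surrogates validated on qualitative contracts. GC content is
taken from supplied sequences or tables, never from a reference genome.
Doublet detection is rule-based (marker co-expression), not model-based;
ambient contamination is out of scope.
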