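# Methods

This note documents the statistical procedures implemented in cardiomap,
the synthetic data they are validated on, the parameter choices that
matter, and the places where the design was genuinely open.

## Synthetic data model

Each of T cell types carries a gene program p_t, a probability vector
over G genes drawn from a sparse Dirichlet (concentration 0.3), with
four reserved gene classes overriding the draw:

* **exclusive markers** — 20 genes per type holding 10% of the program's
  mass in their own type and exactly zero elsewhere; these guarantee
  separable clusters and a well-defined marker truth;
* **ambient-dominant genes** — 30 genes sharing 15% of every program's
  mass identically across types, so they dominate the ambient pool while
  being maximally type-nonspecific;
* **mitochondrial genes** — 13 genes (symbols `MT-*`) with 2% shared mass;
* **condition-effect genes** — 20 per cell type, planted at a base rate
  of 5x10⁻⁴–2x10⁻³ (about 1–4 counts per nucleus at the default depth) in
  every type. In case-condition samples the target type's rate is
  multiplied by 2^(±2) (alternating signs). The base rate is chosen so
  planted genes sit above the pipeline's own low-count exclusion — an
  effect planted on a gene the prefilters are designed to drop would be
  unrecoverable by construction, which would test the generator rather
  than the method.

A nucleus of type t in sample s draws its counts multinomially with
probability (1−a)·p_t + a·m_s, where m_s is the abundance-weighted
mixture of the sample's programs (the ambient pool) and a ~ Beta with
mean 0.10 (concentration 50). Library sizes are lognormal (median
≈ 2,000 UMI, log-sd 0.35) with a per-sample lognormal depth factor
(log-sd 0.15) — the only batch structure simulated. Doublets (5%) are
sums of two independently drawn nuclei. Low-quality nuclei (10%) draw
from their type's program concentrated onto its top 20 genes with 30%
of mass moved to mitochondrial genes, and their exonic-read proportion
is drawn from a Beta with mean 0.30 instead of 0.08 (cytoplasmic
contamination raises the exonic fraction of nuclear libraries).

Cell-type abundances follow a mild gradient (1.67:1 between the most and
least abundant types) so that every type clears the 25-nuclei-per-sample
pseudobulk floor in every sample; a disease-linked composition shift
(type0 x0.55, type1 x1.4 in case samples) emulates the large
cardiomyocyte-loss / fibroblast-gain shifts seen in end-stage heart
failure and is what makes case and control samples separate on
patient-level principal components, as they do in real cohorts.

The "ambient-corrected" matrix subtracts round(a·L·m_s) per gene from
the raw counts and clips at zero — a deterministic expectation
subtraction, not a probabilistic inference; only the existence of a
paired corrected/uncorrected matrix matters downstream. Because
per-nucleus expected ambient counts below 0.5 round to zero, low-rate
ambient leakage survives in both matrices; this is a known limitation
(see below).

**What passing tests show, and what they do not.** The generator
reproduces the statistical structure the pipeline assumes — program-based
types, shared ambient contamination, depth variation, labeled artifact
nuclei, patient-level replication — but not realistic gene-gene
correlation within programs, transcriptional continua, cell-cycle or
stress signatures, or batch effects beyond a depth shift. Recovery rates
measured here certify the procedures' logic and calibration, not their
performance on tissue.

## Quality control

Seven metrics per nucleus; entropy is the plugin estimator
H = −Σ p_g ln p_g in nats (richer estimators change the scale but not
the cascade's logic, which is why the entropy floor is a parameter).
The doublet score embeds observed nuclei together with simulated
doublets (sums of random observed pairs) in one PCA space and reports
the fraction of simulated points among k nearest neighbors, with
k = round(0.5·√n·(1+r)) by default (r = simulated:observed ratio).
Candidate pairs are oversampled 3x and the most dissimilar parents kept:
near-duplicate parents yield simulated profiles indistinguishable from
singlets after normalization, which only dilutes the score (homotypic
doublets are undetectable by any expression-based method regardless).

The cascade first drops whole clusters whose median %MT, exon
proportion or doublet score exceeds — or median entropy falls below — a
Tukey fence over the distribution of cluster medians. The published rule
is qualitative ("elevated levels"), so this fence is a substitution and
configurable. Cluster medians are weighted by cluster size by default:
artifact nuclei tend to shatter into many small pure clusters, and with
unweighted quartiles a third of the clusters being artifacts drags the
fence up to their own level.

The per-(sample, cluster) pass then applies Tukey fences (k = 1.5) per
metric with the stated directions, computed once (single pass). Two
numerical choices: quartiles use linear interpolation between order
statistics (positions 1 + (n−1)q, the common default, oracle-tested),
and a metric whose group IQR is zero while values still differ (heavily
quantized scores) falls back to its hard bound rather than using a
zero-width fence that would reject any nucleus off the modal value. A
group constant on a metric keeps all its nuclei. Groups under 30 nuclei
use the hard thresholds throughout.

**Entropy floor calibration.** The published floor (8) belongs to a
different estimator on a ~20,000-gene universe. With the plugin
estimator on the generator's 2,000-gene programs, clean nuclei sit near
6.3 nats and planted low-quality nuclei near 3.9; the synthetic-pipeline
runs use entropy_min = 5.0, the midpoint implied by those design
parameters. On real data this floor must be recalibrated to the
estimator and gene universe in use.

## Clustering and the halt rule

Highly variable genes are ranked by observed/expected variance around a
quadratic mean-variance trend fitted in log10 space (a lighter stand-in
for the loess-based standardized variance; the downstream recovery, not
the exact gene list, is the validated surface). Scaled values are
clipped at ±10 before PCA. The kNN graph uses cosine similarity edge
weights, symmetrized by union; Leiden uses the RB-configuration
partition at the given resolution with a fixed seed.

The subclustering sweep raises the resolution stepwise. At each step,
every cluster is mapped to the previous-resolution cluster it overlaps
most (its parent); a cluster that shares its parent with siblings must
show a marker gene separating it from those siblings — maximum
one-vs-rest AUC within the parent's nuclei above 0.60. When some new
cluster has none, the sweep halts and the previous resolution's labels
are returned (configurable to return the current labels with failing
clusters marked). The within-parent comparison is essential: scored
against the full dataset, any split of a true type inherits its parent's
markers (AUC ≈ 0.75 from the other types' presence alone) and the gate
could never close in a mixed population.

The sweep can still leave genuine-looking micro-clusters — e.g. the
detectors of one rare, near-binary transcript, which unit-variance
scaling amplifies into a tight blob. These share their parent's mean
profile, and the Ward merge rule (cut at 0.25 x the dendrogram's maximum
linkage height; alternatively 0.25 x the maximum pairwise centroid
distance, by flag) collapses them. Signature scores use the
expression-bin-matched control scheme of the standard `score_genes`
implementation; a subcluster is screened out when its median foreign-type
score exceeds its own-type score or its mitochondrial score exceeds a
fence (absolute, or Tukey over subcluster medians by default).

## Pseudobulk differential expression

Counts are summed per (cell type, sample); columns need ≥ 25 nuclei
(≥ 20 on the marker path) and contrasts need ≥ 3 samples per group.
Prefilters drop genes expressed in < 1% of nuclei in every condition
group (a gene prevalent in one group alone is kept), genes without ≥ 10
summed counts in at least the smaller group's number of columns (a fixed
substitute for the reference tool's adaptive low-count heuristic; both
knobs configurable), and mitochondrial/ribosomal genes by flag or symbol
prefix (`MT-`, `RPS`, `RPL`). Size factors are median-of-ratios over
genes positive in all columns.

The response is log2-CPM of size-factor-normalized counts with
pseudocount 0.5. Per gene, an ordinary linear model with intercept,
treatment-coded condition and standardized covariates (age, sex,
optionally study) is fitted by least squares, vectorized across genes;
covariate columns that are constant or collinear on the available
samples are dropped (condition columns are mandatory). Residual
variances are shrunk toward a common prior by the standard
empirical-Bayes recipe — a scaled-F prior fitted by moments on the log
variances, posterior df added to the residual df — matching the
moderated-statistics framework the procedure descends from; `moderated=
False` gives plain OLS. p-values are two-sided t; BH adjustment is
within each cell type and contrast. All log fold changes are base 2.

Significance requires FDR < 0.05 with the same sign under both count
versions. The fibrosis variant uses the same engine with a continuous
covariate of interest and an unadjusted p < 0.005 in both count versions
(the n = 6 design has little power; the analysis is exploratory by
construction). Marker models use `~0 + cluster + individual` with the
sample indicator as a fixed effect, contrasting each cluster against the
mean of the others.

Under the synthetic null the engine's type-I error at p < 0.05 is
4–5%; with planted |log2FC| = 2 effects at 8 vs 7 samples the
concordance filter reaches ~0.85–0.95 sensitivity at ≤ ~0.1 empirical
FDR. Residual false positives are mostly ambient leakage of genes whose
source types shift in composition between conditions — the artifact
class the background heuristic describes — surviving because the
generator's rounded expectation subtraction cannot remove sub-unit
ambient rates.

## Background heuristic

For target type t: bkg_prob is the fraction of genes whose dataset UMI
fraction is ≤ the gene's own (ties share the upper step; strictly-less
available), computed on raw counts by default (the choice of count
version is configurable; the abundance ranking barely differs).
PPV0/PPV1 dichotomize counts at > 0 and > 1 and are standardized to
prevalence ½ as TPR/(TPR+FPR) — the unique reading in which the type's
prevalence cancels — defined as 0 when the gene is never positive.
heuristic = bkg_prob x (1 − (PPV0+PPV1)/2); flagged above 0.4. Flagged
genes are excluded from enrichment inputs and marked, not deleted, in DE
results. The partitioned variant classifies in-lineage vs rest for
subtype-level testing. On synthetic data all planted ambient-dominant
genes are flagged in every type and no planted exclusive marker is
flagged in its own type.

Note that genes expressed at similar baseline levels in all cell types
score nontarget_prob ≈ 0.5 regardless of any condition effect, so a
pipeline that discarded every flagged gene would also discard genuinely
shared condition-responsive genes; this is why the flag is a mark, not a
removal.

## Cascades and auxiliary tests

Shared-disease genes must be concordance-significant with one sign in
every disease-vs-control contrast, in no disease-disease contrast, with
|logFC| > 1 in all three and expressed in > 5% of nuclei in some group.
Unique-disease genes are significant versus control and versus at least
one other disease. Druggable annotation joins gene symbols to a tier
table; cell-type specificity uses the gene's one-vs-rest AUC in that
type above 0.6 — no threshold is stated in the source procedure, so the
marker-gene gate is reused. Enrichment is a one-sided Fisher/
hypergeometric test with set-size bounds and two significance modes
(unadjusted p < 0.001 with odds ratio > 2, mirroring graph-conditioned
term testing where a correction is deliberately not applied; or BH
FDR < 0.05). Probe-pair selectivity requires AUC > 0.6, logFC > 1,
> 20% target expression and ≤ 25% in every other population, then ranks
candidates by target minus maximum off-target double-positive rate with
the pan-lineage marker. Proteomics concordance classifies by each
platform's significance and sign agreement, first protein row winning on
duplicate symbols. The composition test replaces a Bayesian
compositional model with per-sample log2 ratios to a reference type
(pseudocount 0.5), two-sample t-tests per type and BH across types —
same reference convention, far lighter machinery; the interface accepts
any external implementation.

## Problem sizes

Validation runs use desk-scale designs chosen to exercise every rule:
3,000 nuclei (15 samples x 200) for QC/clustering/background recovery,
3,750 (15 x 250) for DE recovery, 2,500 genes x 15 samples for null
calibration, 7,250 nuclei for the three-disease cascade, and full
enumeration of 2x2 tables at small margins for the exact-test oracle.

## Known limitations

* The plugin entropy and simulated-doublet score are deliberate
  simplifications; their absolute scales differ from the heavier
  published estimators, so their thresholds are parameters.
* The expectation-based ambient correction leaves sub-unit leakage; a
  probabilistic correction would change dual-count concordance behavior.
* The DE engine is a moderated linear model on log2-CPM without
  precision weights; very low counts are handled by prefiltering rather
  than by observation-level weighting.
* Harmony-style batch integration is a hook (`embed(batch_align=...)`),
  not an implementation; the generator's only batch effect is depth.
* The halt rule's within-parent AUC check needs clusters large enough
  that a maximum over genes of a null AUC stays below the gate
  (roughly ≥ 300 nuclei per compared side at 500 genes).
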