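# Methods

`stemscore` re-implements, as a tested and reusable pipeline, a single-cell
analysis of staged mammary-tumor progression: compartment-specific quality
control, clustering, cancer-signature construction and per-cell scoring,
median-split classification of normal versus cancer cells, identification of
a stem-like (BCSC) cluster, stage-wise proportion dynamics with a trend test,
survival stratification, and cytokine–receptor cross-talk. Real staged
atlases of this kind exist only as large sequencing deposits, so the
package ships a synthetic-data generator with planted ground truth; every
claim the test suite makes is a claim about recovery of planted structure,
not about any particular biological dataset.

## The synthetic-data generator

`simulate_single_cell` draws gamma–Poisson (negative binomial) counts:
for mean μ and dispersion d, variance = μ + d·μ². Structure:

- **Stages.** Four progression stages, W07/W09/W11/W17 (hyperplasia →
  adenoma/MIN → early → late carcinoma in the modeled system), 500 cells per
  stage by default. A single global seed drives a per-stage `SeedSequence`
  spawn so stages are independently reproducible.
- **Compartments.** 60% epithelial / 40% immune per stage. Library sizes are
  lognormal with mean 12,000 (epithelial) and 3,500 (immune), σ = 0.45;
  mitochondrial fractions are Beta-distributed with mean 0.04 / 0.05 and
  concentration 60. These choices emulate the real-data contrast that
  motivates compartment-specific QC and put roughly 80–90% of cells inside
  their compartment's gates.
- **Cell types.** Six marker-defined types (three luminal/basal epithelial
  types, a stem-like epithelial type, T cells, macrophages). Each type has
  25 marker genes at a low baseline abundance weight (0.08) multiplied by a
  fold change of 40 in its own type, so markers are near-silent elsewhere
  (fraction expressing ≈ 0.2) and high in their own type (≈ 0.95). Named
  markers carry the field's gene symbols (Esr1/Foxa1/Gata3/Pgr for the
  ER-high luminal type; Cxcl1/Cxcl16/Cd24a/Procr for the stem type;
  Cxcr6 on T cells, Cxcr2 on macrophages) so the ER-lineage and cross-talk
  stages operate on realistic identifiers.
- **Cancer signature.** 30 up- and 30 down-regulated genes are planted;
  cancer cells multiply/divide them by `signature_effect` (default 8).
  The per-stage cancer fraction among epithelial cells rises
  0.2 → 0.4 → 0.6 → 0.8, and cancer flags are assigned *stem-first*: every
  stem-like cell becomes cancerous before any non-stem epithelial cell.
  This makes early-stage cancer entirely stem-derived and keeps the overall
  epithelial cancer fraction near 50%, the regime in which a median split is
  an accurate classifier. The gene universe (names, markers, planted
  signature, baseline abundances) is a deterministic function of the seed
  alone, shared between the single-cell and bulk generators — bulk DE must
  recover exactly the genes shifted in single-cell cancer cells.
- **Bulk replicates.** `simulate_bulk` draws tumor and normal groups over
  the same universe (4 replicates/group in the shipped pipeline, depth
  3×10⁵) with NB dispersion 0.05 — matched-animal bulk replicates are far
  less dispersed than single cells.
- **Survival cohort.** `simulate_cohort` plants a "high" half of subjects
  whose signature genes are 3-fold elevated and whose exponential event
  hazard is multiplied by the hazard ratio; censoring is independent
  exponential with rate `baseline · c/(1−c)`, giving ≈ c censored at hazard
  ratio 1 and exactly zero censoring at c = 0.

Not simulated: doublets, ambient RNA, batch effects, transcriptome-wide
correlation. Passing tests therefore demonstrate the pipeline's statistical
machinery and its recovery of planted effects under an idealized noise
model, not robustness to those artifacts.

## QC

`compute_qc_metrics` reports library size, detected genes and mitochondrial
fraction (genes recognized by the `mt-` prefix; `MT-` for human data is a
flag). `filter_cells` applies strict inequalities exactly as the criteria
are written: epithelial cells need counts > 5,000, genes > 2,000,
mitochondrial fraction < 8%; immune cells counts > 1,000, genes > 500,
mito < 8%; the human preset genes > 400 and < 7,000, mito < 20% with no
total-count bound (implemented literally). Boundary cells are removed.
Removal counts are reported per criterion, counting a cell once under every
criterion it fails.

## Normalization, embedding, clustering

Log-normalization is ln(1 + count·10⁴/total) per cell; highly variable genes
are the 3,000 largest-variance genes of the log-normalized matrix (ties by
gene id; a mean-standardized variant is available); scaling is per-gene
z-scores clipped at ±10; PCA keeps 50 components (full SVD, each component's
sign fixed so its largest-magnitude loading is positive — deterministic
across LAPACK builds). Clustering builds a k = 20 nearest-neighbor graph,
converts it to shared-nearest-neighbor Jaccard weights pruned below 1/15,
and runs seeded Leiden under the RB-configuration quality function at
resolution 0.4. Singleton communities are absorbed into their
most-connected cluster (nearest centroid if disconnected), as the common
single-cell toolkits do; labels are contiguous integers ordered by
decreasing size. No covariate regression is performed before PCA.

On the default configuration the epithelial chain recovers the planted
expression profiles — the cell type × cancer status combinations, which are
the generator's actual mixture components — with adjusted Rand index
≈ 0.98 (the test floor is 0.8). Cancer status is a planted transcriptional
state, so clusters legitimately split cell types by it.

## Differential expression and signatures

Single-cell DE is a per-gene two-sided Wilcoxon rank-sum test with midrank
ties: the tie-corrected normal approximation with continuity correction for
min(n_A, n_B) > 8, and an exact enumeration of the rank-sum null otherwise
(a subset-sum counting recursion on doubled midranks; the exact branch is
limited to pooled sizes ≤ 200, beyond which the approximation is accurate).
Fold change uses `expm1` of mean log-normalized expression with pseudocount 1.

Bulk DE normalizes with TMM (reference = sample whose upper-quartile
expression is closest to the mean; 30% two-sided M-trim, 5% A-trim,
inverse-variance weights, factors rescaled to multiply to 1 — verified
against edgeR's `calcNormFactors` to 1e-6 in the tests) and tests
log2-CPM (pseudocount 0.5) with an empirical-Bayes variance-moderated t:
per-gene pooled variances are shrunk toward a scaled-inverse-χ² prior fitted
across genes by moment matching on log variances. The moderation is the
package's deliberate choice for 3–6-replicate designs, where the plain
Welch t has so few degrees of freedom that genome-wide FDR control leaves no
discoveries; `moderated=False` restores the ordinary Welch test. Genes with
zero counts in every sample are excluded from the BH background.

Signature gates are strict: up-genes need FDR < 0.05 and fold change > 1.5,
down-genes FDR < 0.05 and fold change < 0.67. Curated marker genes are
merged into a signature's up-set by simple union (a curated gene found in
the down-set moves to the up-set, logged). A cluster is called ER-high when
the fraction of its cells with nonzero Esr1 exceeds 0.5 (configurable;
such calls are usually made by eye from an expression map, so there is no
canonical threshold).

## Scoring and classification

The cancer score per cell is mean(up-genes) − mean(down-genes) on
log-normalized expression. The stemness score is a single-sample
weighted-KS rank enrichment score: genes are ranked by decreasing expression
(midranks for ties), in-set steps are proportional to
(N + 1 − rank)^τ (τ = 1 by default) normalized over the set, out-of-set
steps are −1/(N − n), and the score is the maximum positive plus minimum
negative deviation of the walk ("maxdiff"), bounded in [−1, 1] and
invariant under monotone transforms of a cell's expression. This is a
deliberate re-implementation of the GSVA-style statistic in single-sample
form; the original algorithm's kernel-density rank conditioning is out of
scope, and all guarantees are stated as planted-signal recovery, not
numeric equality with that package.

Cells strictly above the median cancer score are "cancer", the rest
"normal" — the boundary cell at the median is conservatively normal.
The stem-like cluster is the cluster with the highest mean stemness score
(ties broken by label order and flagged); BCSCs are operationally the
cancer-labelled members of that cluster. Proportion dynamics report, per
stage, |label ∩ denominator| / |denominator| with missing values (not
zeros) for empty denominators. Under the generator's stem-first rule the
BCSC share of cancer cells *declines* with stage — early cancer is entirely
stem-derived, later cancer is not — and the per-stage median cancer score
rises.

## Trend and survival statistics

Mann-Kendall: S = Σ_{i<j} sign(x_j − x_i), tie-corrected variance
[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18, ±1 continuity-corrected z. Because
the test is applied to as few as four stage medians — where the normal
approximation is crude — an exact permutation p is also reported for short
series: by a Mahonian inversion-count recursion when values are distinct,
or by enumerating the distinct orderings of the multiset when there are at
most 2×10⁵ of them. One-sided alternatives ("increasing"/"decreasing") are
provided and matter in practice: with four medians the two-sided exact p
can never fall below 1/12, so a planted monotone increase is only
detectable one-sided (exact one-sided p = 1/24 at the perfect ordering).
The pipeline's stage trend uses the increasing alternative.

Kaplan–Meier estimation and the two-group log-rank test delegate to
lifelines, with events preceding censorings at tied times (a subject
censored at an event time is at risk for that event). Survival
stratification splits subjects at the median of mean expression over a
signature's up-genes (strictly above → high), the same boundary rule as the
cell-level split. Calibration on simulated cohorts (n = 200, 20% censoring,
200 Monte-Carlo replicates): empirical size 0.02–0.09 at hazard ratio 1,
power ≥ 0.9 at hazard ratio 3.

## Cross-talk

For each ligand/receptor gene of a pair list, the per-cluster mean
log-normalized expression and expressing fraction are tabulated (the
numbers behind a dot plot). A (pair, source, target) triple is flagged when
the ligand passes fraction ≥ 0.1 and across-cluster z-score ≥ 1 in the
source and the receptor does likewise in the target; the score is the sum
of the two z-scores. This rule is an explicit operationalization of visual
dot-plot inspection; both thresholds are configuration knobs with no claim
to being canonical values. The shipped pair TSV is a
small generic stand-in list (including Cxcl1–Cxcr2 and Cxcl16–Cxcr6), not a
curated repository.

## Numerical and design notes

- All strict-inequality boundaries (QC gates, DE gates, median splits) are
  implemented exactly as written; boundary cases are tested explicitly.
- Exact tests (rank-sum, Mann-Kendall) are verified against exhaustive
  enumeration oracles to 1e-12 in the acceptance suite.
- Degenerate inputs are handled by convention and logged: all-equal scores →
  everything "normal"; zero-variance zero-difference genes → p = 1; no
  events → log-rank statistic 0, p = 1; empty stage denominators → missing.
- The problem sizes used by the tests and the acceptance script (5,000 genes
  × 2,000 cells for the full pipeline; 2,000 × 2,000 for score recovery;
  200 Monte-Carlo replicates for calibration; 50 seeds for cross-talk) were
  chosen as the smallest sizes at which the planted effects are comfortably
  identifiable; all complete in a few minutes on one CPU.
- Known limitations: the simulator's independence assumptions flatter any
  clustering method; the moderated t is not a negative-binomial test and
  will be conservative for very low counts; the rank-ES score is not
  numerically interchangeable with GSVA's; jackstraw component selection is
  replaced by a fixed 50 components.
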