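# Methods

## Overview

`glycoscape` quantifies glycolytic activity in bulk tumors and single cells
with a rank-based single-sample enrichment score, stratifies cohorts on that
score, and asks which genomic, transcriptomic and clinical features travel
with it. Because the analyses it implements were designed for large public
multi-omics cohorts, the package ships a generative model of that data
structure (`glycoscape.simulate`) so that every downstream claim can be
tested against planted ground truth.

## Single-sample enrichment scoring

The engine (`glycoscape.gsva`) maps a genes × samples matrix of log2(TPM+1)
values to per-sample, per-signature scores in [−1, 1] in three steps.

1. **Kernel CDF.** Each gene's cross-sample distribution is estimated
   non-parametrically. With the Gaussian kernel the value of gene *i* in
   sample *j* becomes `mean_k Φ((x_ij − x_ik)/h_i)` with bandwidth
   `h_i = SD_i · bandwidth_factor`; `bandwidth_factor` defaults to 1/4, the
   convention for log-scale expression. `kernel="none"` substitutes the plain
   ECDF. Genes with zero variance get a floor bandwidth of 1e−8 so constant
   housekeeping rows degrade to ties instead of NaNs.
2. **Symmetric rank statistic.** Within each sample, genes are ranked by
   decreasing CDF value (ties broken by input gene order, so results are
   deterministic). The statistic `r = |p/2 − rank|` weights genes by their
   distance from the middle of the ranking.
3. **Weighted random walk.** Walking the ranked list, in-set genes add
   `|r|^τ` normalized by the in-set total (τ = 1 by default) and out-of-set
   genes subtract `1/(p − k)`. The score is the maximum positive deviation
   minus the magnitude of the maximum negative deviation; each term lies in
   [0, 1], so the score is bounded in [−1, 1] with no secondary rescaling.

Numerical notes. Exact invariance under strictly increasing per-gene
transforms holds for the ECDF path, where only ranks enter; the
Gaussian-kernel path is only approximately invariant because its bandwidth
depends on the per-gene scale. Signature genes absent from the matrix are
dropped with a warning and the overlap actually used is reported; scoring
refuses sets with zero or complete overlap. Scores are computed per cancer
type by default (`score_per_group`), matching the per-cohort classification
design; pooled scoring is used for cross-cancer comparisons, since per-type
scoring centers each cohort by construction.

## Signatures

Three signatures ship as a packaged GMT file: a 22-gene glycolysis panel of
core pathway enzymes and the GLUT1 transporter; a 14-gene hypoxia-response
panel; and a 16-gene glycolysis variant with the six genes shared with the
hypoxia panel (ALDOA, ENO1, LDHA, PGAM1, SLC2A1, TPI1) removed, used to show
the glycolysis–hypoxia score correlation is not an artifact of shared
membership.

## Cohort stratification and clinical analyses

`classify_by_score` labels the top and bottom `floor(q·n)` samples of each
cancer type (q = 0.30) high/low, breaking boundary ties by ascending
(score, sample_id) so group sizes are exact and deterministic; cohorts whose
groups fall below 30 samples are flagged ineligible. Splits are computed on
tumor samples only. Tumor-vs-normal contrasts use the rank-sum test and run
only in cancer types with ≥30 normals; the stage contrast is Welch's t
between stage IV and stage I.

Survival uses in-package implementations with explicit conventions:
Kaplan–Meier product-limit curves; the two-group log-rank test with pooled
ties and hypergeometric variance; and Cox proportional hazards fitted by
Newton–Raphson on the Breslow partial likelihood (convergence when the max
coefficient step < 1e−8, limit 50 iterations; covariates are centered for
conditioning; singular information or constant covariates raise rather than
return silent zeros). lifelines serves as an independent cross-check in the
test suite, not as the implementation. The multivariate model defaults to
glycolysis score, hypoxia score and ordinal stage; the covariate list is a
config option because no single canonical set exists.

## Genomic association

Within each cancer type, a gene's cohort-level CNA direction is called from
the gain/loss sample-count ratio: ratio > 2 calls the direction; a zero
denominator with nonzero numerator counts as exceeding 2 (the limit of the
rule); 0/0 is ambiguous. Score associations compare altered vs
copy-number-neutral samples (gains and losses separately) with Welch's t —
chosen over the pooled test because arm sizes and variances differ wildly —
and BH adjustment within each cancer type, never pooled across types. Genes
with fewer than 5 altered samples (configurable) are skipped as vacuous.
SNV associations collapse mutation multiplicity to presence/absence of a
nonsynonymous mutation. The driver panorama tests gains for oncogenes and
losses for tumor suppressors and ranks drivers by the number of cancer
types with directional p < 0.05 (ties by mean |Δscore|, then name).
TMB is the raw per-sample nonsynonymous count (not per-megabase): the
normalization constant is irrelevant for rank tests. Aneuploidy uses
Spearman correlation; genome-doubling classes (0/1/2) use a k-sample test,
as the three-group design requires.

## Transcriptome screen

Differential signature enrichment between high and low groups uses Welch's
t on per-sample enrichment scores (these are approximately normal around
zero, so a moderated-t machinery adds little) with BH across signatures.
Differential expression uses the rank-sum test on log2(TPM+1) with fold
change computed as the ratio of mean linear TPM+1 values (pseudocount kept
for stability at zero); a gene is "up" only conjunctively — linear fold
≥ 1.5 *and* adjusted p < 0.05. A negative-binomial count model is
deliberately not used: the inputs are TPM-scale, not raw counts.
Cross-cancer recurrence keeps genes "up" in ≥ k cancer types (k = 13 at the
25-type scale; the analysis scripts scale k to the simulated cohort count).
Candidate genes are ranked by their median per-cancer Spearman correlation
with the glycolysis score — the ranking key had to be chosen here, and the
median is robust to a single outlying cohort; min/max rho are reported
alongside. Over-representation (`ora_test`) is an upper-tail hypergeometric
test against any user-supplied GMT, reported as enriched only with overlap
≥ 3 genes and p < 0.01.

Quadrant stratification splits samples at the hypoxia-score median (top 50%
= H+), then at the chosen gene's expression median within each H stratum
(G±), with the same lexicographic tie rule; per-quadrant summaries and
pairwise Welch tests of any target variable are emitted.

## Single-cell branch

QC removes cells with < 200 total counts, < 200 or > 6000 expressed genes,
or > 10% mitochondrial counts ("MT-" symbol prefix, configurable), and the
report records which rule each removed cell failed; the filter is
idempotent. Counts are normalized to log2(1 + CP10K). A variance-stabilizing
transform is unnecessary here because scoring is rank-based per gene, and
any monotone per-gene transform yields identical ECDF ranks. Cells then flow
through the same scoring engine as bulk samples; top-30% overlay flags
(exactly `floor(0.3·n)` cells per score or gene) are emitted as a table
joinable to any embedding — clustering and t-SNE are out of scope. Spatial
contrasts run one-way ANOVA per patient across core/edge/middle regions,
with patients lacking two regions of ≥ 2 cells skipped explicitly.

## Synthetic data model

Each tumor carries latent activities (g, h) ~ bivariate normal with
correlation ρ (default 0.8, the strongly coupled regime); normals sit at
the zero baseline and tumors are shifted +1 latent SD. Signature genes load
on their latent with `sig_effect` = 1.0 log2 units per latent SD and
residual noise 0.4 log2 units; the six shared genes load half on each
latent, reproducing the overlap-confounding structure; all other genes are
noise. These two values were fixed so that the 22-gene score tracks the
latent tightly (rank correlation ≈ 0.99), which makes ρ directly
interpretable as the target score-level correlation — the scoring map adds
essentially no attenuation, and the shared-gene loading raises the observed
score–score correlation slightly above ρ (≈ 0.84 at ρ = 0.8), with the
overlap-free 16-gene score at ≈ 0.77.

Planted drivers shift carriers' g; driver effects are parameterized on the
latent scale, where the calibrated latent→score regression slope is ≈ 0.52,
so an effect stated on the score scale converts by that factor. Survival
times are exponential with hazard ∝ exp(hazard_beta·g) (default log 2 per
latent SD) under independent exponential censoring; stage is an ordered
logit on g; aneuploidy is discretized g-correlated noise (ρ = 0.4);
doubling classes are an ordered split of a g-linked latent. Single cells
are negative binomial (dispersion 0.5) on exp(baseline + 0.8·latent), with
region-dependent hypoxia means (core > middle > edge), five mitochondrial
genes, and a 5% fraction of deliberately corrupted cells (count-thinned or
mitochondria-boosted) with recorded identities so QC can be verified
exactly.

Defaults — 4 cancer types × 300 tumors + 50 normals, 400 genes, 8 patients
× 90 cells — are small enough to run interactively yet large enough that
the ≥30-sample eligibility rules bind. What the generator does *not*
emulate: realistic gene–gene co-expression beyond the two latent programs,
segment-level CNA structure, batch effects, or cell-type mixtures. Passing
recovery tests therefore demonstrates correctness of the pipeline's
inference under its assumed data model, not robustness to every real-data
pathology.

## Problem sizes used in validation

The validation suite runs the engine-vs-oracle check on 200 small random
matrices; score bounds on 1000 matrices; null centering on a 5000-gene ×
100-sample matrix with 1000 random 22-gene sets; correlation recovery on
100 cohorts of 500 tumors; FDR calibration on 200 null replicates of 2000
genes; driver power on 200 cohorts of 500 tumors; log-rank size on 5000
null replicates; and the end-to-end determinism check on the default
bundle, twice. `scripts/acceptance.py` recomputes the same quantities at
reduced replicate counts chosen to keep a single run under a few minutes.

## Known limitations

- The Gaussian-kernel path is not exactly invariant under monotone
  transforms (see above); use `kernel="none"` when exact rank invariance
  matters.
- The rank-sum DE test does not model count overdispersion; it is the
  appropriate choice for TPM-scale input but will differ from
  count-model results near the significance boundary.
- Cox fitting uses Breslow ties; with heavily tied time scales (e.g.,
  month-rounded follow-up) Efron-style handling would be less biased.
- Over-representation depends entirely on the user-supplied GMT; no pathway
  database is bundled.
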