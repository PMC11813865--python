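# Methods

This note documents the models behind each stage, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic-data tests do and do not demonstrate about real data.

## Study design and labels

Two independent cohorts, each sampled at sea level (SL, 50 m) and after
24 h at high altitude (HA, 4,300 m). Severity is a **subject-level,
time-invariant** label: a subject whose AMS-C cerebral factor score at HA
is ≥ 1.4 (inclusive) is severe (AMS+), and that label applies to both
their SL and HA samples — the four sample groups (AMS+/AMS− × SL/HA) are
defined by crossing this label with timepoint. The four biomarker
contrasts are:

| category   | comparison                   | design              |
|------------|------------------------------|---------------------|
| diagnostic | AMS+ vs AMS− among HA samples| unpaired, sex-adjusted |
| predictive | AMS+ vs AMS− among SL samples| unpaired, sex-adjusted |
| pathogenic | SL → HA within AMS+ subjects | paired (subject blocks) |
| protective | SL → HA within AMS− subjects | paired (subject blocks) |

Paired designs include one indicator column per subject; sex is constant
within subject and therefore omitted there (it would be collinear). In
unpaired designs, if the selected samples happen to be single-sex the sex
covariate carries no information and is dropped with a log note; genuine
confounding of sex with the group is rejected as a rank-deficient design.

## Preprocessing

* **Sample QC**: a sample is removed when its fraction of genes with raw
  count < 10 strictly exceeds 0.2 ("more than 20%"). Both inequalities
  are strict; a sample at exactly 20% is retained.
* **Masking + imputation**: surviving counts < 10 become missing. Each
  missing entry is replaced by the average of the same gene's values in
  the `k = 5` nearest samples among those observing the gene. Distance is
  the **mean** squared difference of log2(count+1) over genes observed in
  both samples — the mean (not sum) keeps attrition-shortened overlaps
  comparable. `k` is configurable; 5 is a conventional small-neighborhood
  default for expression imputation. Imputation runs per cohort: cohorts
  are separate sequencing batches, and cross-cohort neighbors would leak
  batch signal into imputed values. Genes observed in no sample are
  dropped with a warning. Imputed (real-valued) matrices are rounded to
  the nearest integer before model fitting, since the NB likelihood needs
  integers; the imputed fraction is small (typically < 10% of entries),
  so rounding error is far below count noise.
* **TMM normalization**: per-sample factors against a reference sample
  (the one whose 75th-percentile count fraction is closest to the mean of
  those fractions). Gene-wise log2 ratios M and average abundances A are
  computed on genes nonzero in both samples; the top and bottom 30% by
  M-rank and 5% by A-rank are discarded; the factor is 2 to the
  precision-weighted mean of the surviving M, with inverse-variance
  weights from the binomial delta method; factors are rescaled to
  geometric mean 1. Ties in the trim ranks are handled by average ranks.
  A factor within 1e-10 of 0 on the log scale snaps to exactly 1. The
  implementation agrees with an independent brute-force enumeration of
  the trimming rule to 1e-10, and with edgeR's `calcNormFactors` on spot
  checks.
* **log-CPM**: log2((count + 0.5) / (effective library + 1) × 1e6); used
  for PCA and as classifier features, never for testing.
* **PCA check**: samples beyond 3 SD on PC1 or PC2 are reported, not
  removed — outlier handling is an analyst decision.

## Negative-binomial differential expression

Counts are modeled NB with mean μ and variance μ + φμ². Per-gene GLMs
(log link, log effective library size as offset) are fitted by IRLS,
vectorized across genes. The contrast coefficient divided by ln 2 is the
log2 fold change; the p-value is the likelihood-ratio χ² test (1 df) of
the contrast column against the reduced design. Non-convergent genes are
flagged and assigned p = 1; coefficients are clamped at |log2FC| ≤ 30 so
separated groups (one group all zeros) produce a finite, flagged
estimate. Genes with zero counts in more than 90% of a contrast's samples
are excluded from testing. BH correction is applied within contrast over
tested genes.

**Dispersion.** The Cox–Reid adjusted profile likelihood
APL_g(φ) = ℓ_g(β̂(φ)) − ½ log det(XᵀWX) is evaluated on a log-spaced grid
of 25 φ values in [1e-4, 4] with warm-started fits. The common φ_c
maximizes the mean APL across genes; gene-wise φ_g maximizes each gene's
APL; the shrunk value maximizes APL_g(φ) + (prior_df / residual df) ·
mean-APL(φ). Grid maxima are refined by a parabola in log φ, and the
shrunk estimate is clamped to the interval between φ_g and φ_c — a
numerical constraint that makes the shrinkage interpolation exact at both
limits (prior_df → ∞ gives φ_c everywhere). `prior_df = 10` by default: a
deliberately strong prior, because with ≤ 18 subjects per cohort
gene-wise dispersions are badly underestimated and unshrunk fits are
anti-conservative. This is a re-implementation of the standard
NB-GLM/APL analysis, not a call into edgeR; agreement is validated
distributionally (type-I error within [0.03, 0.07] at nominal 0.05,
uniform null p-values, fold-change recovery) rather than bit-wise, and
the Poisson limit (φ = 0) reproduces statsmodels' Poisson GLM LRT to
1e-6.

**DEG thresholds**: p < 0.05 and |log2FC| > 0.7, both strict. FDR is
reported but not used for calling, matching the candidate-list
definition; the replication requirement across cohorts is the error
control.

## Cross-cohort replication

`common_degs` intersects the tested gene universes (logged when they
differ), applies the DEG thresholds in each cohort, and keeps genes whose
fold-change signs agree. On null synthetic data the expected number of
surviving genes is well below 1 per 2,000 — replication across
independent cohorts is a far stronger filter than either cohort's p-value
alone, which is the methodological point of the two-cohort design.

## Classifier panels

* **Labels**: for the diagnostic panel, positives are HA samples of
  severe subjects; every other sample (their SL samples, and all samples
  of resistant subjects) is negative. On the emulated design this yields
  the 5/31 training and 4/12 validation splits. For the predictive panel
  only SL samples are used, labeled by the subject's eventual severity.
* **Ranking**: random forest (10,000 trees, √p features per split,
  bootstrap size n, grown to purity, fixed seed) on the discovery cohort;
  importance is mean decrease in Gini impurity (node impurity 1 − Σp²),
  ties broken lexicographically by gene ID.
* **Panels**: for k = 1..N, a linear SVM (L2-regularized hinge loss,
  C = 1, inverse-class-frequency weights, unregularized bias) is trained
  on the top-k genes, standardized by training mean/SD only — no
  information flows from the validation cohort. Class weighting matters:
  at 5 positives vs 31 negatives an unweighted fit can collapse to the
  majority class.
* **Evaluation**: validation-cohort ROC over all distinct thresholds; AUC
  equals the Mann–Whitney pair statistic (ties count ½). The best panel
  maximizes AUC with the smallest k on ties; the operating point
  maximizes J = sensitivity + specificity − 1, ties toward higher
  sensitivity.

## Synthetic-data generator

Gene baseline abundances are log-normal (ln-mean 5.0, ln-SD 1.2, chosen
so a 2,000-gene transcriptome yields ~10⁶ counts per sample and only a
few percent of counts fall below the masking threshold); counts are
gamma-Poisson with a single global dispersion φ = 0.1, a typical bulk
RNA-seq value for human cohorts; library sizes are log-normal (σ = 0.15).
Default cohorts reproduce the emulated study's accounting: 18 paired
subjects (5 severe) and 10 subjects (5 severe) with attrition to 9 SL +
7 HA samples, leaving 4 severe subjects with an HA sample — the
published validation split. AMS-C scores are drawn as 1.4 + |N(0.4, 0.3)|
for severe and U(0, 1.3) for resistant subjects; only the dichotomy
matters downstream. A sex effect (default 1 log2 unit on 50 genes) gives
the sex covariate something to absorb, and a configurable fraction of
genes (default 5%) is forced into the < 10-count regime to exercise
masking and imputation.

Planted effects are multiplicative on the NB mean: diagnostic genes shift
only in (severe, HA) samples; predictive genes in severe subjects at both
timepoints; pathogenic genes SL→HA in severe subjects; protective genes
SL→HA in all subjects. Magnitudes default to 1.2–2.0 log2 units, anchored
to the published candidate fold changes (0.7–3.5). Planted genes draw
their baselines from the upper half of the abundance distribution —
hemoglobin-like, matching the highly expressed candidates they emulate —
which also keeps a planted down-shift identifiable instead of censored by
the low-count mask.

**What the generator does not model**: gene–gene correlation (real
co-expression modules), gene-wise dispersion variation (available as an
option but off by default), batch effects, exercise as a covariate
(one cohort exercised during exposure; treated as a limitation, not
modeled), and cell-type composition shifts in PBMCs. Passing recovery
tests therefore demonstrate correctness of the machinery under the
assumed NB model, not expected sensitivity on real cohorts.

## Problem sizes in tests

Calibration and recovery tests run at the emulated design's own scale
(2,000 genes, 36 + 16 samples) over 25 seeds; oracle-equivalence checks
use 100–150 random small instances each; forest-based unit tests use
reduced tree counts (200–2,000) where ranking stability, not the printed
10,000-tree default, is the property under test.

## Known limitations

* The NB engine approximates, rather than reproduces, edgeR's exact
  numerics (no quantile-adjusted conditional likelihood, no spline grid);
  p-values match distributionally but not digit-for-digit.
* KNN imputation biases masked group differences toward neighbors'
  values; genes whose true signal lives below the masking threshold in
  one group are partially censored. This is a property of the published
  preprocessing recipe itself, visible in the synthetic recovery runs.
* With 4–5 positive samples in a cohort, AUCs are coarse (steps of
  1/(n₊·n₋)); reported operating points should be read accordingly.
* Real-data DEG counts and panel AUCs from the original cohorts are not
  reproducible here without the cohort data; the shipped reference tables
  cover only the published candidate-gene statistics.
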