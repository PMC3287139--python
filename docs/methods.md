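# Methods

`chemomir` reimplements, as a tested library and pipeline, a miRNA-based
analysis of chemoresistance in metastatic gastric cancer: a diagnostic
cancer-vs-normal expression signature, a per-miRNA proportional-hazards
screen against time to progression (TTP) under cisplatin/fluorouracil
chemotherapy, a supervised principal-component survival risk predictor with
percentile-based risk grouping and permutation-tested cross-validated
Kaplan–Meier separation, and a paired pre/post-treatment evaluation of
acquired resistance. All stages run end to end on synthetic cohorts whose
structure mirrors the motivating study design.

## Data model and preprocessing

Expression arrives as a feature-by-sample matrix of log2 sample/reference
ratios from a two-channel array in which every mature miRNA is printed as 4
replicate probes. Preprocessing comprises:

- **log2 transform** of positive raw ratios (masked entries stay masked);
- **lowess normalization** per array on M-vs-A coordinates (M = log2 ratio,
  A = mean log2 intensity): the normalized value is M minus the lowess fit
  of M on A. Defaults follow the classical smoother — span 2/3, 3
  robustifying iterations — and are configurable. At least 10 unmasked
  probes are required per array. Note that local-regression normalization is
  only approximately idempotent: a second pass changes values on the order
  of the smoother bias (well under 0.05·SD(M) in our tests), not to machine
  precision.
- **replicate collapsing** to the median of unmasked replicates per miRNA
  per sample (median rather than mean for robustness to single bad spots);
  a collapsed value is masked only when every replicate is masked;
- **missing-value policy**: features masked in more than 50% of samples are
  dropped before any statistic; remaining holes are imputed with the
  feature's median across samples.

All tables are plain TSV ('.' decimal, empty cell = missing); matrices are
features × samples everywhere.

## Differential signature and class prediction

Per-feature differential expression uses the classical pooled-variance
two-sample t-test with two-sided p-values; the reported ratio is
2^(mean_cancer − mean_normal) of the log2 values, so overexpressed features
have ratio > 1. FDR is Benjamini–Hochberg (the standard step-up; stated in
output headers since the upstream tooling left the method unnamed).
Zero-pooled-variance features are flagged and excluded rather than assigned
a p-value.

Predictive power is estimated by repeated random class-stratified 1:1
training/test partitions (default 100). Within each partition, features are
re-selected on the training half only (t-test p < α, default 0.05) and six
classifiers are fitted:

- **CCP** (compound covariate predictor): covariate c = Σ tᵢxᵢ over selected
  features with t-statistic weights; threshold at the midpoint of the class
  mean covariates;
- **DLDA**: Gaussian discriminant with feature-specific pooled variances and
  zero covariances, equal priors;
- **1-NN / 3-NN**: Euclidean distance on the selected features;
- **NC**: nearest class centroid, Euclidean;
- **SVM**: linear kernel, cost 1, features standardized by training
  mean/SD.

The per-classifier median test accuracy over partitions is the headline
statistic. Stratification makes a single-class training half impossible at
the study's class sizes.

## Survival screening

Each miRNA is screened with its own univariate Cox proportional-hazards
model of TTP (continuous covariate, no dichotomization). Ties are handled
by Efron's approximation (tied event times arise in month-resolution data),
p-values come from the Wald test, and Newton iteration runs to a score
(gradient) below 1e−8. Monotone partial likelihoods (|β| escaping past 15)
and constant covariates are flagged and excluded from selection.
Features with p < α are split by hazard direction: HR > 1 joins the
chemoresistance list (overexpression ↦ rapid progression), HR < 1 the
chemosensitivity list; BH-FDR is computed over all tested features.

The screen is a compiled (numba) per-feature Newton kernel because the
permutation machinery below re-runs it inside every leave-one-out fold of
every permutation replicate — on the order of 10⁵–10⁶ single-feature fits
per analysis. The kernel is validated against `lifelines.CoxPHFitter` on
tied and untied data and against brute-force maximization of an
independently written partial likelihood.

## Supervised-PC risk predictor

Following the supervised principal-component approach, the fitted model is:

1. screen features by univariate Cox at α (default 0.05; 0.01 exposed);
2. center the selected-feature submatrix by training means (no variance
   scaling — components of the log intensities themselves);
3. take the first two principal components of the centered
   samples-by-features submatrix;
4. fit a Cox regression of TTP on the two PC scores → (β₁, β₂);
5. the predictive index of a sample x is PI = β₁u₁ + β₂u₂ with
   u_k = Σᵢ V_ik (xᵢ − mᵢ) — equivalently a weighted sum of centered log
   intensities with weights w = Vβ (stored; the two routes agree to 1e−10).

High PI ⇒ rapid progression. A new sample is ranked on the training PI
distribution by midrank percentile — 100·(#{<} + ½#{=})/n — so the training
median maps to exactly 50%; it is called **high-risk** when its percentile
strictly exceeds the cutoff (default 67, the study's split; the boundary
convention is ours, as no sample in the motivating data sat exactly on it).

**Cross-validated significance.** Leave-one-out cross-validation refits the
*entire* model (screening, PCs, Cox) on each n−1 fold and assigns the
left-out sample a group from its fold-specific percentile; folds with fewer
than two screened features (or a degenerate PC Cox fit) assign low risk and
are counted. The two-group log-rank chi-square of the cross-validated
groups, LR_d, measures separation; its significance is the tail probability
of LR_d under joint reshuffling of the (TTP, event) pairs across samples
(expression fixed), re-running the full LOOCV per permutation:
p = (1 + #{LR_perm ≥ LR_d})/(1 + n_perm), default n_perm = 1000. A run in
which every sample lands in one group contributes LR = 0. This permutation
reference is essential: the null distribution of a cross-validated log-rank
statistic is not chi-square.

## Paired pre/post evaluation

Pairs are scored against the model fitted on the training cohort only
(never refit with pair samples). A pair is **overall correct** when the
post-treatment sample's PI is strictly greater than the pre-treatment
sample's (ties are incorrect — the criterion requires a *higher* index);
the pre-treatment call is low/high risk from its percentile. Summary output
reports the pre-treatment low-risk fraction and the overall-correct
fraction.

## qPCR ΔΔCt

Duplicate wells are averaged before any subtraction; ΔCt = mean target Ct −
mean RNU6 Ct per sample; ΔΔCt = ΔCt_test − ΔCt_control with the control
baseline defaulting to the mean ΔCt of the normal group (a designated
control sample is configurable). Relative expression is 2^(−ΔΔCt); fold
changes are reported on the log2 scale as −ΔΔCt (fold change −1 = 50%
decrease). Group comparison is a pooled-variance Student t-test on the
log2-scale fold changes — the log2 scale is the deliberate choice here,
since the linear scale would break baseline invariance and the fold-change
convention is a log2 convention. Re-baselining to another control shifts
all values equally and leaves the test invariant (tested). No
amplification-efficiency correction or multi-reference normalization is
attempted.

## Synthetic cohorts: what they emulate, and what not

`SimulationConfig` defaults encode the study conditions: 1,667 mature
miRNAs × 4 replicate probes, 90 cancer + 34 normal samples for the
diagnostic signature, an 82-patient survival training set, and 8 pre/post
pairs. Technical replicate noise has SD noise_sd/2 (replicates must be more
alike than biological samples for collapsing to matter); biological log2
values are Normal(0, noise_sd²), noise_sd = 0.5.

- **Differential signature**: 125 planted features (the size of the
  study's differential table) shifted ±1 log2 unit in cancer, half up and
  half down.
- **Hazard signature**: 58 planted features (the size of the study's
  TTP-associated list; alternating signs give a 29/29 resistance/
  sensitivity split) with per-feature log-hazard coefficients
  β = ±0.06 per log2 unit. The planted features share a per-sample latent
  activity factor, sign-aligned with their effect direction
  (`hazard_factor_corr` = 0.5; marginals stay Normal(0, noise_sd²)). This
  co-expression is deliberate and load-bearing twice over: real signature
  miRNAs are co-transcribed in polycistronic clusters, and the supervised-PC
  method's own data model assumes signal features share the latent risk
  factor — with fully independent planted features the top two PCs of the
  screened block retain only ≈ 2/k of the risk direction and the method is
  structurally powerless, which would say nothing about real data.
- **Survival times**: event ∼ Exponential(λ₀·exp(r)) with latent risk
  r = Σβⱼxⱼ, independent Exponential censoring. λ₀ and the censoring rate
  are *calibrated* (Gauss–Hermite expectation + root find) so the observed
  TTP median is 3.1 months with 20% censoring regardless of the planted
  risk spread; with no signal this reduces to the closed form
  λ₀+λ_c = ln2/3.1. The 20% censoring fraction is a free parameter of the
  emulation, not an inference from the study. TTP is kept continuous
  (months); Efron ties are nevertheless implemented and tested.
- **Pairs**: pre-treatment samples are rejection-sampled from the low-risk
  half of the latent score (the study's pairs came from clinical
  responders); the post sample is the pre sample moved `pair_shift` (default
  2) log2 units along the unit-normalized fitted resistance direction, with
  fresh technical noise.

Not emulated: scanner/spatial artifacts, dye bias (the generator emits
already-normalized log ratios; lowess is exercised on constructed M–A
fixtures), batch effects, clinical covariates, and any real miRNA
identities. Passing tests therefore demonstrate the statistical machinery —
calibration, power at planted effect sizes, internal identities,
determinism — not performance on real clinical data.

## Numerical choices

- Newton convergence: score < 1e−8; step clipped to ±2 (univariate) /
  norm 5 (multivariate); |β| > 15 flags a monotone likelihood.
- PCA via SVD; loading signs fixed by making each vector's
  largest-magnitude entry positive (PI is invariant to the choice).
- Percentiles use midranks so ties split evenly.
- Risk-group boundary: strictly greater than the cutoff ⇒ high.
- kNN ties break by smallest distance, then training order (the sklearn
  convention); 2-class 3-NN majority votes cannot tie.
- All randomness flows through one integer seed per generator call;
  pipeline stages draw child seeds from the master seed via
  `SeedSequence`. Reruns are byte-identical.

## Problem sizes in the test suite

The statistical acceptance tests run at the study's cohort sizes where the
cost is a single fit (selection-rate calibration at 500 features × n = 82;
classifier protocol at 300 features, 90 + 34 samples, 100 partitions;
power/recovery at 300 features × n = 82 over 40 replicates). The
permutation-calibration study — 100 replicates × 100 LOOCV pipelines each —
uses 60-feature, 60-sample null cohorts, and permutation power uses 20
replicates at n_perm = 99: calibration of a permutation p is a structural
property (exchangeability of the observed statistic with its permutation
null), not a function of problem size, and these sizes keep the whole suite
in the minutes range.

## Known limitations

- The generator's Gaussian, cluster-correlated expression model is far
  simpler than real miRNA data (no heavy tails, no array batch structure).
- Only two principal components are supported, as in the method emulated;
  no elastic-net/lasso Cox alternatives.
- The 8-pair evaluation is a proof-of-principle design with no power for
  formal testing, and is reported as counts, not inference.
- The 67% cutoff is treated as a given constant of the emulated protocol.
- The permutation p is Monte-Carlo discrete (resolution 1/(n_perm+1)).
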