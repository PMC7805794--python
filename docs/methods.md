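# Methods

This note documents the models, numerical choices and known limitations of
`dnamclocks`, in the order a cohort flows through the package.

## Age transform

Clock training and prediction operate on a transformed chronological age
F(a) that is logarithmic up to the adult-age knot A and linear beyond it,
with the +1 offsets that make the two branches meet at F(A) = 0:

    F(a) = log((a+1)/(A+1))   for a ≤ A
    F(a) = (a−A)/(A+1)        for a > A

A defaults to 20 years but is a parameter of `TransformSpec`, so
sensitivity analyses can move the knot. The inverse is exact and the
round-trip error is at machine precision (the test suite requires < 1e-9 y
over ages 0–120). Blood-style clocks that predict years directly use the
`identity` transform.

## Clock application

DNAm age is the inverse-transformed linear score b₀ + Σ bⱼβⱼ over the
clock's sites. Practical details:

- **Missing sites.** Applying a 450K-trained clock to EPIC data (or any
  filtered matrix) loses probes. Policies: `impute_reference_mean`
  (default; substitutes the clock's stored training-set mean beta, so the
  imputed term contributes exactly what an average observed value would),
  `drop_site` (omits the term, no rescaling) and `error`. A sample missing
  more than `max_missing_fraction` (default 0.2) of the clock's sites is an
  error under every policy, and the per-sample missing count is reported.
- **Range overshoot.** Normalization can push betas slightly outside
  [0, 1]; values are clipped before scoring, with a warning.
- Prediction is invariant to site and sample order, and for
  identity-transform clocks exactly affine in each beta.

Δ (delta) age is predicted minus chronological age: a clock that
under-predicts in old donors has negative Δ there.

## Clock training

Elastic net on raw beta values with an unpenalized intercept:

    (1/2n) Σᵢ (F(ageᵢ) − b₀ − xᵢᵀb)² + λ[α‖b‖₁ + (1−α)/2‖b‖₂²]

- **α = 0.5** by default (equal lasso/ridge mix); exposed.
- **Predictors are not standardized**: betas share the common [0, 1] scale,
  so penalizing coefficients on that scale is meaningful and keeps the
  published-clock convention of coefficients applying to raw betas.
- **λ grid**: 100 log-spaced values from λ_max (smallest λ with an all-zero
  solution, computed from the centred data as max|Xᵀy|/(n·α), with the
  usual small-α floor at 1e-3 to keep the pure-ridge limit finite) down to
  λ_max·1e-4.
- **Cross-validation**: K = 10 folds; folds group samples **by donor** by
  default, because donors contributing multiple cortical regions would
  otherwise leak between training and validation and bias λ low. The whole
  descending path is fitted per fold with warm-started coordinate descent
  (scikit-learn's solver, whose objective is exactly the one above with
  their `alpha` = λ and `l1_ratio` = α), so the CV curve exists at every
  grid point. λ is chosen by `cv_min` (default) or `one_se`.
- **Probe pre-filter**: training restricts to probes flagged present on
  both the 450K and EPIC platforms with no missing values across training
  samples, mirroring how cross-platform clocks must be built.
- The returned clock stores only the nonzero-coefficient sites, with
  training-set site means as reference means for later imputation. At full
  shrinkage the clock is intercept-only (mean transformed age); this
  degenerate but well-defined clock is representable and predicts a
  constant.

Solver contracts enforced in tests: equality with closed-form OLS at
near-zero λ (1e-4 tolerance on a 20×5 instance), intercept-only at huge λ,
penalized objective at the solution below zero-vector/OLS/coordinate
perturbations, and a non-increasing sparsity trend along the λ path.

## QC and normalization

All filters only remove rows/columns (retained values untouched) and are
idempotent; quantile normalization is the only value-modifying step.

- **Bisulphite conversion**: per-sample precomputed percentage; samples
  strictly below 80% are excluded (boundary kept). The statistic itself is
  intensity-level chemistry and out of scope — it arrives via the sample
  sheet.
- **Detection p filter**: samples with strictly more than 1% of probes at
  p > 0.05 are removed first; then probes failing in strictly more than 1%
  of the remaining samples. Strict inequalities follow the thresholds'
  usual phrasing; boundary cases are kept.
- **Sex check**: classical (Torgerson) multidimensional scaling of
  inter-sample Euclidean distances on X-chromosome probes and Y-chromosome
  probes separately; two-means split on the first coordinate of each. The
  cluster with the larger between-sample variance of Y-probe betas is
  labelled male — in females Y probes carry only tight near-zero
  background. Samples on which the X- and Y-based partitions disagree, or
  all samples when a coordinate is degenerate, are `undetermined` rather
  than guessed.
- **Genotype concordance**: Pearson correlation of SNP-probe betas
  (trimodal at genotypes ≈ 0/0.5/1) for every sample pair; r ≥ 0.9 is
  called same-individual. Same-donor pairs below threshold are mismatches,
  different-donor pairs above it duplications.
- **PCA outliers**: samples beyond 3 SD (default, exposed) on any of the
  first three principal components of the site-centred matrix. In the
  pipeline the scan runs on autosomal non-SNP probes only: genotype and
  sex clusters would otherwise own the leading components and mask
  technical outliers. Note that a 3-SD rule has an irreducible false-flag
  rate of roughly 1% of samples on Gaussian data; the threshold is a knob,
  not a guarantee.
- **Quantile normalization** emulates between-array normalization of
  methylated and unmethylated intensities: within each probe chemistry
  type (I/II), each channel is separately replaced by the rank-wise mean
  distribution across samples, then β = M/(M+U+100). The
  background-equalization step that full dasen-style normalization
  performs before quantile normalization operates on intensity internals
  not represented here and is deliberately omitted.

Pipeline order: conversion → sex check (flags) → genotype concordance
(flags) → detection-p filter → PCA outliers → blacklist probes. Flag-only
steps never silently remove samples.

## Evaluation and bias profiling

Pearson's r and RMSE (√mean squared Δ) are the headline accuracy numbers.
Age-dependent bias is profiled with equal-frequency deciles of
chronological age (stable sort, ties fill the lower bin; equal-width bins
available as a flag) and per-decile five-number summaries of Δ age with
1.5·IQR whiskers. `variance_explained` is the marginal fixed-effect R² of
the age-association model, which reduces to Pearson r² in the
one-sample-per-donor OLS case.

## Association models

DNAm age is regressed on age (optionally + age²), or on a covariate of
interest adjusted for age, age² and neuronal proportion (the proportion is
dropped from the adjustment set when it is itself the covariate; extra
fixed effects such as brain bank can be added and categorical covariates
are dummy-coded). A per-donor random intercept is used whenever any donor
has more than one sample, fitted by REML; otherwise plain OLS.

Approximation contract: fixed-effect p-values for the mixed model are Wald
tests on the normal approximation. Satterthwaite-style t degrees of freedom
would be preferable in small samples; at the n ≥ 300 sizes these analyses
run at, the two are numerically interchangeable (the type-I calibration in
the acceptance run measures ≤ ~1% rejections at the 0.005 threshold over
200 null fits). Age² uses uncentred age by default (centring is a flag and
changes only the linear term's interpretation). The multiple-testing
threshold p < 0.005 is a labelled flag in every report, never silent
filtering. Marginal R² for mixed fits is var(Xb) / (var(Xb) + σ²_donor +
σ²_resid).

## Synthetic cohorts

The generator emulates the structure a cortical clock study assumes: donors
spanning ages 1–108 (uniform, or Beta(5, 2)-skewed toward old age to mimic
dementia-cohort demographics), several regions per donor sharing age, sex
and genotype, sparse age-associated CpGs, bounded beta noise, optional
per-batch offsets, trimodal SNP probes and sex-differential X/Y probes.

**Age-site model.** Age-associated sites are linear in transformed age on
the beta scale, βⱼ(a) = midⱼ + cⱼ·(F(a) − F_mid), with each slope shrunk so
the noiseless trajectory stays inside [0.02, 0.98] over the configured age
range — betas are bounded *by construction*, and the returned generating
clock (weights cⱼ/Σc², matching intercept) inverts the model exactly: at
zero noise it reproduces every age to machine precision, which anchors the
generative-consistency tests. A logit-link formulation was considered and
rejected: it also bounds betas, but no linear clock can invert a sigmoid
exactly, so exact zero-noise recovery — the property the engine's tests
lean on — would be unattainable. The cost of the linear choice is a rank-1
noiseless signal subspace: all age sites are perfectly collinear, which is
*harder* for support recovery than real data (the elastic net may pick any
predictive subset), and causal-site recall of ~0.6–0.8 should be read with
that in mind. Measurement noise is Gaussian on the beta scale, clipped to
(0, 1); defaults (noise sd 0.02, slope spread 0.05 per unit transformed
age) give life-course beta ranges of ~0.1–0.3 at age sites, in line with
strong clock CpGs.

**What passing tests do not show.** The generator has no probe-level
covariance beyond the shared age axis, no nonlinear methylation
trajectories (real trajectories saturate in old age — one reason real
clocks under-predict there even when trained on the full range), no
platform/chemistry artefacts and no disease structure. Results on it
validate the machinery, not real-data performance.

**Defect injection** plants labelled QC failures — detection-p failures on
2% of a sample's probes, a flipped sex label, redrawn SNP genotypes for one
sample of a multi-sample donor, a 10-SD shift on up to 200 probes, a 79.9%
conversion value — so QC recall and precision are measurable ground truth.

## Experiment sizes

The recovery experiment trains on 400 samples (250 donors × 2 regions,
minus 50 held-out donors) over 2000 sites with 50 causal and is replicated
three times; the truncation-bias experiment uses 700 donors (400-sample
training pool, 300 evaluation samples) at moderate signal-to-noise
(noise sd 0.06, 20 causal sites of 1000), because a near-noiseless cohort
fits essentially exactly everywhere and cannot exhibit prediction bias;
the null-calibration experiment runs 200 mixed-model fits at n = 300.
These sizes are the package's reference configurations for desk-scale
replication and are what `scripts/acceptance.py` runs.

## Known limitations

- Intensity-level QC (signal checks, conversion chemistry, control-probe
  layout) is out of scope; those metrics enter as precomputed numbers.
- The packaged clock tables are synthetic stand-ins (see README); analyses
  requiring the real published coefficients must supply them.
- The sex check assumes both sexes are present; single-sex cohorts come
  back undetermined rather than labelled.
- Mixed-model p-values use the normal approximation (above).
- The truncation-bias experiment reproduces the *mechanism* (a clock
  trained without old donors under-predicts old ages far more than a
  full-range clock, whose own mild attenuation at the extremes mirrors the
  small negative age² curvature even well-calibrated clocks show); it does
  not reproduce any real cohort's effect sizes.
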