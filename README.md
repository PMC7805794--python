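# dnamclocks

Tools for the full lifecycle of DNA-methylation (DNAm) age clocks in human
cortex: apply published CpG-coefficient clocks to beta-value matrices, train
new elastic-net clocks on transformed chronological age, run the tabular
QC/normalization steps typical of Illumina 450K/EPIC studies, and profile
clock accuracy and age-dependent bias.

## Who this is for

Epigenetics groups working with post-mortem brain methylation arrays, where
the standard blood-trained clocks are known to drift: clocks trained on a
tissue or age range different from the target cohort systematically
under-predict age in old donors, which can masquerade as "age acceleration"
phenotypes. This package provides the machinery to apply, retrain and audit
such clocks on your own cohorts, plus a synthetic-cohort generator so every
step is testable without any external download.

## The model

An epigenetic clock is a sparse linear predictor over CpG methylation
proportions (beta values, β ∈ [0, 1]). For a sample with betas βⱼ at the
clock's sites,

    s = b₀ + Σⱼ bⱼ βⱼ

is the clock score. Life-course clocks are trained on a transformed age that
is logarithmic before adulthood and linear after (adult age A = 20):

    F(a) = log((a+1)/(A+1))   a ≤ A
    F(a) = (a−A)/(A+1)        a > A

so DNAm age = F⁻¹(s); blood-style clocks predict years directly (identity
transform). Δ (delta) age = DNAm age − chronological age is the signed
prediction error.

Training solves the elastic net on raw betas with an unpenalized intercept:

    min  (1/2n) Σᵢ (F(ageᵢ) − b₀ − xᵢᵀb)²  +  λ [ α‖b‖₁ + (1−α)/2 ‖b‖₂² ]

with α = 0.5 and λ chosen by grouped 10-fold cross-validation (donors
contributing several cortical regions never straddle a fold). Accuracy is
profiled by Pearson's r and RMSE; age-dependent bias by equal-frequency
age-decile summaries of Δ age and by mixed-effects regressions of DNAm age
on age and age² with a per-donor random intercept.

## Packaged clock fixtures

Four coefficient tables ship under `dnamclocks/data/`: a 347-site cortical
clock and 353/514/513-site multi-tissue, blood and pheno-age comparators,
with the cortical clock sharing 5, 15 and 5 sites with them respectively.
**These are synthetic stand-ins** (placeholder probe IDs and coefficients
that preserve the published site counts and overlap structure, regenerable
via `scripts/make_synthetic_clock_fixtures.py`); swap in real published
tables in the same TSV layout for production use.

## Worked example

Simulate a cohort, train a clock on 300 of its samples, score the rest:

```
dnamclocks simulate --seed 11 --n-donors 200 --regions-per-donor 2 \
    --n-sites 1000 --n-age-sites 40 --out-dir sim
head -3 sim/samples.tsv
```
```
sample_id       age     sex     donor_id        region  batch   pmi_hours       neuronal_proportion     bisulphite_conversion_pct
donor0000_region1       14.757011696304358      M       donor0000       region1 batch1  7.8     0.5406  96.55
donor0000_region2       14.757011696304358      M       donor0000       region2 batch2  77.5    0.4318  96.04
```
```
dnamclocks train --betas sim/betas.tsv --samples sim/samples.tsv \
    --seed 1 --out-clock clock.tsv
dnamclocks predict --clock clock.tsv --betas sim/betas.tsv \
    --samples sim/samples.tsv --out pred.tsv
dnamclocks evaluate --predictions pred.tsv --samples sim/samples.tsv \
    --out-dir eval
cat eval/metrics.tsv
```
```
metric  value
pearson_r       0.999044
rmse_years      1.36601
variance_explained_r2   0.99808
n       400
```

Here the trained clock tracks chronological age with r ≈ 0.999 and an RMSE
of ≈ 1.4 years on the simulated cohort (training-set numbers; the held-out
figures from a donor-level split are what `scripts/acceptance.py` reports).
`eval/deciles.tsv` holds the per-decile Δ-age box statistics used to
diagnose age-dependent bias. The same operations are available as library
functions (`dnamclocks.fit_elastic_net_clock`, `predict_dnam_age`,
`decile_error_summary`, …).

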