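# Methods

## Data model and imputation

A cohort is one row per woman: case/control status, enrollment age, eight
questionnaire-based epidemiologic factors, an optional PRS, and carrier flags
for pathogenic variants in nine genes.  Missingness is explicit (NaN; empty
cell in the CSV dialect: comma-separated, UTF-8, `.` decimal, 0/1 booleans).

Imputation follows the convention of case-control risk-model work in this
setting:

* each missing epidemiologic value (and missing enrollment age) is replaced
  by the **mean of observed values among participants of the same status** —
  for binary factors this yields a fractional value (the group prevalence),
  which the linear predictor accepts; nothing is rounded back to 0/1;
* missing PV carrier flags are recoded to 0 (non-carrier), since carrying a
  pathogenic variant is far rarer than not.  This deliberately understates
  risk for unsequenced carriers — more so among cases, who are enriched for
  carriers — and therefore attenuates measured model performance; the
  sensitivity path (`exclude_missing`) drops incomplete rows instead.

BMI is stored and imputed as a continuous value and only binned into its four
categories at encoding time; imputing the continuous value and then binning
is the only order in which a "mean" is well defined.

## Covariate encoding

* parity → linear spline with a knot at one child: `first_live_birth`
  (1 if parity ≥ 1) and `additional_live_births` (`max(parity − 1, 0)`), so
  the encoded contribution is continuous in parity at the knot;
* height → per 10 cm, centered at 160 cm;
* BMI → indicators for <18.5, 25–29.9, ≥30 (reference 18.5–24.9 emits none);
* age at menarche and breastfeeding months → continuous, centered at
  configurable reference values (defaults 15 years and 0 months) carried in
  the coefficient file, so that LP = 0 describes an explicit reference woman;
* binary factors pass through (possibly fractional after imputation).

Enrollment age is **not** a term of the relative-risk model; it enters only
as the starting age of the absolute-risk projection.

## Family-history attenuation

Adding a PRS and PV terms to a model that already contains family history
double-counts heritability.  Writing `β_k`, `f_k` for a variant's per-allele
log-OR and allele frequency, the genotype correlation of ½ between
first-degree relatives induces, to first order under a rare-disease logistic
model, a family-history log-OR of `cov(G_proband, G_relative) · β_k² =
f_k(1−f_k) β_k²` per variant.  The attenuated coefficient is therefore

```
β_FH^adj = max(0, β_FH − Σ_k f_k (1 − f_k) β_k²)
```

over the SNVs and PVs active in the model variant (one half of the
Hardy–Weinberg polygenic variance `Σ_k 2 f_k (1−f_k) β_k²`).  The test suite
verifies this magnitude against an independent simulation of
proband–relative genotype pairs.  When the PRS is consumed as a single score
with no per-SNV weight file — the pipeline default — the SNV sum is not
computable variant by variant, and the score-level equivalent
`½ · Var(PRS) · β_PRS²` is used with the control-sample PRS variance; under
independent SNVs the two accountings are identical.  The unadjusted `β_FH`
is retained so the operation is idempotent and can be re-applied per variant.

The attenuation is floored at zero: a panel explaining more familial risk
than the observed family-history coefficient would otherwise produce a
protective family history, which has no epidemiologic support.

## Baseline calibration and absolute risk

The baseline hazard is calibrated **non-iteratively**: with controls as the
reference distribution, `λ0(t) = λ_pop(t) / mean_i exp(LP_i)`, constant in
`t` on the relative-risk side.  The reference here is a single
cross-sectional control sample with no age-varying covariate distribution to
track, so the age-attrition-weighted refinement used by full absolute-risk
frameworks has nothing to bite on; the testable contract is the calibration
identity `mean_i λ0(t) e^{LP_i} = λ_pop(t)` at every age, which holds to
machine precision.

Projection uses an annual grid on [18, 80) with the standard discrete-time
competing-risk decomposition: total hazard `h(t) = λ(t) + m(t)`, within-year
event probability `1 − e^{−h(t)}`, allocated to breast cancer with the
cause fraction `λ(t)/h(t)` (taken as 0 when `h(t) = 0`), and survival carried
multiplicatively.  This is exact when hazards are piecewise constant on
years, which is also how banded rate tables are expanded (each year of age
inherits its half-open band's rate; files carry rates per 100 000
person-years).

Projection starts at each woman's enrollment age by default (a fixed common
start age is a config option; reported mean lifetime risks depend on this
choice).  Women aged 80 or older have an empty projection window and risk 0
in the vectorized pipeline path; the scalar operation rejects ages outside
[18, 80).

## Evaluation

* **AUROC**: Mann–Whitney estimator via midranks (ties count ½), variance by
  DeLong's structural components, Wald 95% CI clipped to [0, 1].
* **Age-adjusted AUROC**: nonparametric stratified placement values with
  10-year age bins by default.  For each case, the placement value is the
  proportion of same-stratum controls scoring above her (ties ½); the
  adjusted AUROC is 1 minus the mean placement value over all cases in usable
  strata, weighting cases equally.  Strata lacking either group are dropped
  with a logged warning.  The CI is a seeded stratified bootstrap (cases and
  controls resampled independently within stratum; 1000 replicates by
  default; the seed is mandatory — no silent nondeterminism).  A parametric
  ROC-regression adjustment would give comparable but not identical numbers;
  the stratified estimator was chosen because it is distribution-free and
  verifiable by enumeration.
* **Threshold summaries / reclassification**: half-open binning
  (`thr_j ≤ risk < thr_{j+1}`), per-status cross-tabulations, and the
  categorical NRI `(up_case − down_case)/n_case − (up_ctrl − down_ctrl)/n_ctrl`.
* **Rounding**: reported percentages are rounded half away from zero to one
  decimal, only at the reporting layer.

## Synthetic data: what it emulates and what it does not

The marginal generator reproduces, per status: truncated-normal continuous
covariates (age ≥ 18, parity rounded and non-negative, breastfeeding ≥ 0)
with the *truncated* mean solved to match the configured target; Bernoulli
binaries and PV carriers; a normal PRS (control mean 0.182, SD 0.314; case
mean 0.268, SD 0.317); per-field missingness rates matching the observed
counts; and status-differential PV missingness (57.2% of cases, 41.2% of
controls unsequenced) mimicking differential panel-sequencing coverage.
Control-side PV frequencies are kept slightly above zero (e.g. 0.3% for
*BRCA1*) to avoid degenerate infinite odds ratios in generated data.

Covariates are drawn **independently within status** — only marginal
distributions are available to configure them — so real-world correlations
(age with parity and breastfeeding, height with BMI) are absent.  Passing
tests on these data therefore validate the pipeline's arithmetic and
calibration, not the joint-distribution behavior of any real cohort.

The rate table generator produces a smooth unimodal incidence curve on
5-year bands over [18, 80), scaled so the peak band equals a configurable
peak (default 64.6 per 100 000, a published age-specific peak for Nigeria,
at age 55 with a 15-year width), and Gompertz-type competing mortality
(5·10⁻⁴ per year at 18, growing 7%/year).  These are stand-ins: actual
registry rates are not publicly printed, so absolute-risk levels produced
here (mean lifetime risks around 1–2%) characterize the synthetic
conditions, not any population.

Generative mode draws a source population from the control marginals,
computes true combined-model LPs with a documented default coefficient set
(plausible placeholder values on the published effect-size scale — not
estimates from any study), calibrates a baseline to the rate table against
that population, and simulates disease/death year by year to enrollment age
plus a 10-year horizon (defaults: population 200 000).  Incident subjects
become cases enrolled at onset age; the true LP is recorded per subject.
This yields the expected qualitative structure of hospital-based series —
older cases, PRS/PV enrichment among cases — and supports ground-truth
checks: the true-LP AUROC matches the binormal identity, and the combined
model outperforms the epidemiologic-only model whenever genetic effects are
nonzero.

## Numerical choices and degenerate inputs

* `expm1` is used for within-year probabilities; hazards of exactly 0
  short-circuit the cause fraction to 0.
* Category binning uses `searchsorted` with right-open intervals; thresholds
  must be strictly ascending in (0, 1).
* Ties in all rank-based statistics contribute ½ (Mann–Whitney convention).
* Coefficient sets reject genetic terms without a frequency in (0, 1);
  imputation raises when a field is missing for an entire status group (no
  donor mean exists); rate tables reject gaps, overlaps, or coverage short of
  [18, 80).
* All randomness flows through `numpy.random.default_rng` seeded from config;
  end-to-end runs are byte-reproducible under a fixed seed.

## Problem sizes used by the test suite

Oracle tests run at sizes chosen to keep the whole suite fast while leaving
Monte-Carlo error well below the tested effects: the projector is checked
against a 10⁵-replicate life-course simulation on 10 random hazard
configurations; the attenuation formula against 6·10⁶ genotype pairs per
configuration; and ground-truth recovery on ten generative cohorts of 5 000
subjects drawn from populations of 450 000.

## Known limitations

* Independent-covariate synthetic data (above) — no copulas, no
  linkage-disequilibrium-aware genotypes, no pedigrees.
* The ER-subtype hybrid PRS combination is a weighted sum with a configurable
  ER-positive proportion (default 0.6); subtype-specific disease modeling is
  out of scope.
* The age-adjusted AUROC estimator is a documented nonparametric substitute
  for parametric ROC regression; values are comparable, not bit-identical.
* No calibration-in-the-large / expected-observed analysis: there is no
  validation cohort in this setting.
* Coefficients are consumed, never fitted; the shipped defaults are for
  synthetic work only.
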