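# Methods

## The two adiposity schemes

The package compares two operationalisations of obesity on the same
subjects. The first is the WHO BMI convention: five half-open bands
[18.5, 25), [25, 30), [30, 35), [35, 40), [40, ∞) kg/m², obesity at
BMI ≥ 30 for both sexes. The second estimates percent body fat with the
CUN-BAE equation — a quadratic polynomial in BMI with linear age and
sex (0 = men, 1 = women) interactions, fitted to white adults — and
bands it in 5-point steps: men (−∞, 20), [20, 25), [25, 30), [30, 35),
[35, ∞); women (−∞, 30), [30, 35), [35, 40), [40, 45), [45, ∞) %BF,
obesity at ≥ 25% (men) / ≥ 35% (women). All bounds are half-open
[lower, upper) so classification is total and exclusive, and the
boundary value 30.0 kg/m² is obese ("30 or more"). The lowest band is
the reference category everywhere. No rounding happens inside scoring;
report-time rounding is two decimals.

One warning about the equation itself: its %BF is strictly increasing
in age throughout age 18–100 × BMI 18.5–60 (the age-derivative
0.503 − 0.02·BMI + 0.00021·BMI² stays positive), and strictly
increasing in BMI for men, but for women the BMI-derivative
(≈ 3.353 − 0.0544·BMI + 0.00042·BMI·age) turns negative above roughly
BMI 55 in subjects younger than ~70. That non-monotone corner is a real
property of the published polynomial, far outside the bulk of any adult
cohort, but code that assumes global monotonicity in BMI for women will
be wrong; the test suite pins the behaviour down explicitly.

## Inclusion rules

Cohorts are adults (age ≥ 18; "over eighteen" is read inclusively and
is configurable to strict) with BMI ≥ 18.5 kg/m²; pregnant subjects are
excluded when a pregnancy column exists, otherwise the data are assumed
pre-filtered. BMI may be given directly or derived as weight/height²;
when both are present they must agree within 0.1 kg/m². Unparseable
sex/age/BMI excludes the row rather than failing the load, and every
exclusion is logged as (id, reason). Missing covariates survive
loading; complete-case deletion happens at regression time, as in
standard practice, with dropped counts logged.

## Agreement statistics

Pearson R² between BMI and %BF is reported pooled and within the six
sex × age strata (age bands < 50 / ≥ 50, edge configurable). Cohen's κ
is computed on the binary obese/not-obese diagnoses (not the 5-level
categories — the agreement question is about the diagnosis), with the
Fleiss–Cohen–Everitt large-sample variance and a normal-quantile 95%
interval. The source analyses named only "an index of coincidence at
95%"; interpreting it as an asymptotic 95% CI for κ is our choice, and
the estimator is cross-checked against an independent implementation in
the tests. κ is undefined when expected agreement is exactly 1 and the
code raises rather than guessing.

## Risk models

Crude odds ratios come straight from the 2×2 table of each category
against the reference, with Woolf's log-odds 95% interval
exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)); a zero cell makes the row
non-estimable unless the Haldane–Anscombe 0.5 correction is explicitly
requested. Woolf coverage is verified by seeded simulation in the test
suite (~95% at 1000 replicates).

Adjusted odds ratios are exponentiated category coefficients from a
Newton–Raphson logistic fit (statsmodels; relative tolerance 1e-8,
max 100 iterations) of outcome on category indicators plus education,
marital status, tobacco and alcohol as unordered categoricals (most
frequent level as reference; level sets are defined by the data), with
continuous linear age added if and only if the exposure is BMI — the
%BF score already incorporates age, and adjusting for it twice would
attenuate the gradient. Wald 95% intervals. Non-convergence and
(quasi-)separation raise typed errors naming the offending term;
|coefficient| > 30 on the logit scale is treated as separation. A
category with fewer than 5 cases or 5 non-cases is flagged
non-estimable.

## Attributable fraction

Miettinen's case-load formulation over exposure levels,
AFp = 1 − Σ_l pd_l/OR_l (as a percentage), where pd_l is the share of
all cases at level l — the reference level included with OR ≡ 1. This
case-distribution reading (rather than population-distribution
variants) exactly reproduces the published %BF-scheme values from the
published case counts and adjusted ORs, which settles the
interpretation. Odds ratios stand in for relative risks, as is standard
for this formulation with cross-sectional prevalence data. AFp is
strictly < 100 whenever cases exist; negative values (protective
patterns) are returned with a warning, never clamped.

For fitting and AFp on individual data, categories with fewer than
`min_cases = 6` cases are collapsed into the adjacent lower band (N and
n summed, merge recorded in provenance, reference never merged). Six is
chosen so that a 5-case band — too sparse for a stable OR, and left
without an estimate in the published male-diabetes table — folds into
its neighbour; applying the same rule to the published counts
reproduces that table's AFp to ~0.1 point. In summary-table mode the
published rounded aORs are taken as-is, so BMI-scheme AFp values are
reproducible only to about ±0.1 point (hypertension) and the
female-diabetes/BMI value recomputes to ≈ 41.9 rather than the printed
40.38 — the discrepancy is attributable to unrounded aORs or a
different sparse-band treatment upstream and cannot be resolved from
printed numbers alone.

## Synthetic cohort generator

The generator emulates the study population, not any real individual
data: n = 3888 with male fraction 2033/3888; per-sex age from truncated
normals on [18, 95] y with means 50.7/49.6 and SD 15 y; per-sex BMI
truncated at ≥ 18.5 kg/m² with means 26.9/26.3 and SD 4.5. The SDs are
not published; 15 y and 4.5 kg/m² give realistic adult spread and are
config-exposed. Truncated normals are parameterised by their
*post-truncation* mean (the underlying location is solved numerically),
so the generated means match the stated values instead of drifting up
with truncation. Age and BMI pass through a Gaussian copula with a
configurable correlation (default 0 — the joint structure is unknown).
Height is drawn per sex and weight derived as BMI·height², keeping
anthropometry internally consistent.

%BF is computed, never drawn, so the generated data inherit the
equation's sex/age structure; this single fact produces the study's
qualitative signature (pooled R² far below stratified R², %BF obesity
prevalence about three times BMI prevalence) without any tuning.

Outcomes are Bernoulli draws from logit p = β₀ + β₁·%BF (+ optional
covariate effects, zero by default so parameter-recovery tests have a
clean truth). Slopes default to 0.12 (hypertension) and 0.10 (diabetes)
per %BF point, the log of the published top-category adjusted ORs
spread over the ~20-point %BF span between reference and top band;
intercepts (−4.985, −5.365) were solved once by large-sample bisection
so the defaults hit overall prevalences of 28.5% and 12.9% (the study's
case loads). Because outcomes are driven by %BF, the %BF scheme is the
"true" exposure and BMI a noisy proxy — the direction of the published
findings (steeper gradients and larger AFp under %BF) holds in the
synthetic data *by construction*; this is a modelling choice for
testability, not an empirical claim. An alternative outcome mode takes
per-category log-odds on the %BF bands, making true category ORs exact
for coverage studies. Drawing order is fixed (sex, age+BMI, height,
covariates, hypertension, diabetes) from one seeded generator, so
cohorts are byte-reproducible per seed.

What the generator does not emulate: right-skewed BMI (a truncated
normal thins the ≥ 40 kg/m² band relative to a hospital-based sample),
covariate–adiposity confounding, hospital selection effects, and any
real joint age–BMI dependence. Passing tests on synthetic data
therefore validate the machinery and the direction of effects, not the
published magnitudes of R², κ or prevalence, which depend on the
original individual data.

## Problem sizes and tolerances

Exact reproduction checks (crude ORs, AFp from printed inputs) run on
the transcribed tables in milliseconds, with tolerance ±0.01 where
inputs are exact counts and ±0.1 points where printed rounded aORs
enter. The logistic-vs-closed-form identity is checked on 100 random
2×2 tables at relative 1e-6. Parameter-recovery and null-AFp studies
use 100 replicates of n = 20 000 (per-category CI coverage ≥ 90/100;
the null judged on the replicate mean, since a single replicate's AFp
scatters several points through shared reference-category noise).
Qualitative-signature checks run on the default n = 3888 cohort.
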