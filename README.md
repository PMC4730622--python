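# adipofrac

Epidemiological toolkit for comparing two ways of diagnosing obesity —
body mass index (BMI) and estimated percent body fat — and for
quantifying how much of the population burden of hypertension and type
2 diabetes each of them attributes to excess adiposity.

BMI is cheap and reliable but blind to sex and age, and with the same
BMI women and older people carry more fat. The CUN-BAE estimator
(Clínica Universidad de Navarra – Body Adiposity Estimator) predicts
percent body fat (%BF) in white adults from BMI, age and sex:

```
%BF = −44.988 + 0.503·age + 10.689·sex + 3.172·BMI − 0.026·BMI²
      + 0.181·BMI·sex − 0.02·BMI·age − 0.005·BMI²·sex + 0.00021·BMI²·age
```

with age in years, BMI in kg/m² and sex coded 0 for men, 1 for women.
Obesity is BMI ≥ 30 kg/m² under the BMI scheme and %BF ≥ 25 (men) /
≥ 35 (women) under the %BF scheme; each scale is split into five
ordered categories (C1–C5, reference C1 = normal weight).

On top of the scoring the package provides:

* **Agreement statistics** — Pearson R² between BMI and %BF (pooled and
  within sex × age strata), Cohen's κ for the obesity diagnosis with a
  Fleiss–Cohen–Everitt asymptotic 95% CI, percent agreement, and the
  obesity-prevalence ratio between schemes.
* **Category-wise risk** — crude odds ratios with Woolf (log-odds) 95%
  intervals from the 2×2 tables, and adjusted odds ratios (aOR) from
  maximum-likelihood logistic regression on category indicators plus
  education, marital status, tobacco and alcohol (and age, only in BMI
  models — the %BF score already encodes it).
* **Population attributable fraction** (Miettinen's case-load form)
  over exposure categories, as a percentage:

  ```
  AFp = 1 − Σ_l (pd_l / aOR_l)
  ```

  where pd_l is the share of all cases found at exposure level l.
* **Synthetic cohorts** — a seeded generator reproducing the structure
  of a two-sex adult cohort (n = 3888; men mean age 50.7 y, mean BMI
  26.9; women 49.6 y, 26.3) with logistic disease models driven by %BF,
  so the whole individual-level pipeline is testable end to end.
* **Summary-level mode** — transcribed published category tables
  (subjects, cases, crude/adjusted ORs per category) for re-analysis
  without individual data.

## Worked example

```python
from adipofrac import (
    afp_miettinen, cun_bae_percent_bf, generate_cohort, score_cohort,
    agreement_report, fitted_afp,
)

bf = cun_bae_percent_bf(age=50, sex="male", bmi=30.0)
print(f"%BF for a 50-year-old man with BMI 30.0: {bf:.2f}")

# published men/hypertension case loads and adjusted ORs, %BF scheme
cases = [21, 79, 208, 199, 121]
aors = [1, 1.67, 3.80, 6.80, 11.24]
print(f"AFp (men, hypertension, %BF scheme): {afp_miettinen(cases, aors).afp:.2f}%")

cohort = generate_cohort(seed=1)
scored = score_cohort(cohort.data)
rep = agreement_report(scored)
overall = rep[(rep.sex == "all") & (rep.age_band == "all")].iloc[0]
print(f"pooled R2 = {overall['r_squared']:.3f}, kappa = {overall['kappa']:.3f}")
print(f"obesity prevalence: BMI {overall['pct_obese_bmi']:.1f}%, "
      f"CUN-BAE {overall['pct_obese_cunbae']:.1f}%")
for scheme in ("BMI", "CUNBAE"):
    res = fitted_afp(scored, "aht", "male", scheme)
    print(f"fitted AFp, men/hypertension, {scheme}: {res.afp:.1f}%")
```

prints

```
%BF for a 50-year-old man with BMI 30.0: 31.37
AFp (men, hypertension, %BF scheme): 74.03%
pooled R2 = 0.379, kappa = 0.212
obesity prevalence: BMI 20.0%, CUN-BAE 67.8%
fitted AFp, men/hypertension, BMI: 35.5%
fitted AFp, men/hypertension, CUNBAE: 56.0%
```

A man at the BMI obesity threshold is already at 31% body fat — well
past the 25% male cut-off, which is why the %BF scheme classifies far
more people as obese (67.8% vs 20.0% here). The pooled R² is poor while
the κ of the two diagnoses is low, yet within sex-and-age strata the
scales track each other closely (see `agreement_report` rows). Because
disease risk in the generated cohort rises with body fat, the
attributable fraction for hypertension is substantially larger when
exposure is measured by %BF than by BMI — the same ordering the
published summary tables show (74.0% vs 37.0% in men).

The same workflow is available from the shell:

```
adipofrac simulate --seed 1 --out cohort.csv
adipofrac agree    --input cohort.csv --out table1.csv
adipofrac risk     --input cohort.csv --outcome aht --scheme cunbae --sex male --out risk.csv
adipofrac fixtures --out-dir summaries/
adipofrac afp      --summary summaries/men_aht_cunbae.csv
```

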