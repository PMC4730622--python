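"""Seeded synthetic cohorts with the study population's structure.

The generator emulates a two-sex adult cohort of hospital-recruited
white subjects: n = 3888 with 2033 men (mean age 50.7 y, mean BMI
26.9 kg/m²) and 1855 women (mean age 49.6 y, mean BMI 26.3 kg/m²) by
default. Age and BMI are truncated normals joined through a Gaussian
copula (independent by default; a correlation knob is exposed because
the joint age–BMI structure of the original sample is unknown).
Percent body fat is computed — not drawn — via the CUN-BAE equation,
so the generated data inherit its sex and age dependence; that is what
makes the pooled BMI–%BF correlation weak while the sex-and-age
stratified correlations are strong.

Previously-diagnosed hypertension and diabetes are drawn from logistic
models whose default linear predictor rises with %BF (so the %BF-based
classification is the "true" exposure), with intercepts calibrated so
overall prevalence is ≈ 28.5% for hypertension and ≈ 12.9% for
diabetes. An alternative categorical outcome mode with known
per-category log-odds supports parameter-recovery testing. Social and
lifestyle covariates are drawn categorically with zero outcome effect
by default, so regression adjustment is testable against a clean truth.

Everything is driven by one seeded NumPy generator per cohort; the
drawing order is fixed: sex, then (age, BMI), then height, then the
four covariates, then hypertension, then diabetes.
"""

from __future__ import annotations

from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from . import reference_tables
from .adiposity import CATEGORY_LABELS, cun_bae_percent_bf, cunbae_category_labels
from .cohort_io import Cohort

_SEX_WORD = {"male": "men", "female": "women"}


class CovariateSpec(BaseModel):
    levels: list[str]
    probs: list[float]

    @model_validator(mode="after")
    def _check(self):
        if len(self.levels) != len(self.probs):
            raise ValueError("levels and probs must have equal length")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")
        if any(p < 0 for p in self.probs):
            raise ValueError("probs must be non-negative")
        return self


class OutcomeModel(BaseModel):
    """Logistic outcome model on the latent adiposity.

    ``logit p = intercept + slope_bf · %BF + Σ covariate effects`` by
    default; if ``category_log_or`` is given (5 values, reference first
    and necessarily 0) the %BF term is replaced by the log-odds of the
    subject's CUN-BAE category, making the true category odds ratios
    exactly ``exp(category_log_or)``.
    """

    intercept: float
    slope_bf: float = 0.0
    category_log_or: list[float] | None = None
    covariate_effects: dict[str, dict[str, float]] = Field(default_factory=dict)

    @field_validator("category_log_or")
    @classmethod
    def _ref_zero(cls, v):
        if v is not None:
            if len(v) != len(CATEGORY_LABELS):
                raise ValueError(f"need {len(CATEGORY_LABELS)} category log-odds")
            if v[0] != 0.0:
                raise ValueError("reference category log-odds must be 0")
        return v


def _default_covariates() -> dict[str, CovariateSpec]:
    return {
        "education": CovariateSpec(levels=["primary", "secondary", "tertiary"],
                                   probs=[0.45, 0.35, 0.20]),
        "marital": CovariateSpec(levels=["married", "single", "widowed", "divorced"],
                                 probs=[0.55, 0.25, 0.12, 0.08]),
        "tobacco": CovariateSpec(levels=["never", "former", "current"],
                                 probs=[0.45, 0.30, 0.25]),
        "alcohol": CovariateSpec(levels=["none", "moderate", "heavy"],
                                 probs=[0.35, 0.50, 0.15]),
    }


class GeneratorConfig(BaseModel):
    """Cohort-level parameters; defaults reproduce the study conditions."""

    n_total: int = Field(default=3888, gt=0)
    male_fraction: float = Field(default=2033 / 3888, ge=0.0, le=1.0)
    age_mean_male: float = 50.7
    age_mean_female: float = 49.6
    age_sd: float = Field(default=15.0, gt=0)
    age_min: float = 18.0
    age_max: float = 95.0
    bmi_mean_male: float = 26.9
    bmi_mean_female: float = 26.3
    bmi_sd: float = Field(default=4.5, gt=0)
    bmi_min: float = 18.5
    age_bmi_correlation: float = Field(default=0.0, ge=-0.99, le=0.99)
    height_mean_male: float = 1.73
    height_mean_female: float = 1.61
    height_sd: float = Field(default=0.07, gt=0)
    covariates: dict[str, CovariateSpec] = Field(default_factory=_default_covariates)
    # Intercepts calibrated by large-sample bisection so that the default
    # population hits overall prevalences ≈ 28.5% (AHT) and 12.9% (DM);
    # slopes follow the observed top-to-reference adjusted-OR span
    # (~log(OR_C5)/20 %BF).
    aht_model: OutcomeModel = Field(
        default_factory=lambda: OutcomeModel(intercept=-4.985, slope_bf=0.12)
    )
    dm_model: OutcomeModel = Field(
        default_factory=lambda: OutcomeModel(intercept=-5.365, slope_bf=0.10)
    )
    seed: int = 1


@lru_cache(maxsize=64)
def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of the underlying normal such that the [lo, hi]-truncated
    distribution has mean ``target_mean`` (truncation pulls the mean away
    from the location, so the two are parameterised separately)."""

    def mean_error(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return brentq(mean_error, target_mean - 5 * sd, target_mean + 5 * sd, xtol=1e-10)


def _truncnorm_ppf(u, mean, sd, lo, hi):
    """Quantiles of a truncated normal whose post-truncation mean is ``mean``."""
    loc = _truncnorm_loc(float(mean), float(sd), float(lo), float(hi))
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=sd)


def _linear_predictor(model: OutcomeModel, bf, cunbae_cat, covs: pd.DataFrame):
    eta = np.full(bf.shape, model.intercept, dtype=float)
    if model.category_log_or is not None:
        log_or = dict(zip(CATEGORY_LABELS, model.category_log_or))
        eta += np.vectorize(log_or.__getitem__)(cunbae_cat)
    else:
        eta += model.slope_bf * bf
    for cov, effects in model.covariate_effects.items():
        eta += covs[cov].map(effects).fillna(0.0).to_numpy()
    return eta


def generate_cohort(config: GeneratorConfig | None = None, **overrides) -> Cohort:
    """Draw one cohort; deterministic given ``config.seed``.

    Keyword overrides are applied on top of ``config`` (or the defaults),
    e.g. ``generate_cohort(n_total=20000, seed=7)``.
    """
    if config is None:
        config = GeneratorConfig(**overrides)
    elif overrides:
        config = config.model_copy(update=overrides)
        config = GeneratorConfig(**config.model_dump())  # re-validate

    rng = np.random.default_rng(config.seed)
    n = config.n_total
    male = rng.random(n) < config.male_fraction
    sex = np.where(male, "male", "female")

    # age and BMI through a Gaussian copula so the correlation knob and
    # the rho=0 default share one code path (and one draw order)
    rho = config.age_bmi_correlation
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    u_age, u_bmi = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])
    age = np.where(
        male,
        _truncnorm_ppf(u_age, config.age_mean_male, config.age_sd, config.age_min, config.age_max),
        _truncnorm_ppf(u_age, config.age_mean_female, config.age_sd, config.age_min, config.age_max),
    )
    bmi = np.where(
        male,
        _truncnorm_ppf(u_bmi, config.bmi_mean_male, config.bmi_sd, config.bmi_min, np.inf),
        _truncnorm_ppf(u_bmi, config.bmi_mean_female, config.bmi_sd, config.bmi_min, np.inf),
    )
    height = np.where(
        male,
        rng.normal(config.height_mean_male, config.height_sd, size=n),
        rng.normal(config.height_mean_female, config.height_sd, size=n),
    ).clip(1.3, 2.2)
    weight = bmi * height**2

    covs = pd.DataFrame(
        {
            name: rng.choice(spec.levels, size=n, p=spec.probs)
            for name, spec in config.covariates.items()
        }
    )

    bf = cun_bae_percent_bf(age, sex, bmi)
    cunbae_cat = cunbae_category_labels(bf, sex)
    aht = rng.random(n) < expit(_linear_predictor(config.aht_model, bf, cunbae_cat, covs))
    dm = rng.random(n) < expit(_linear_predictor(config.dm_model, bf, cunbae_cat, covs))

    data = pd.DataFrame(
        {
            "id": [f"S{i + 1:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "height": height,
            "weight": weight,
            "bmi": bmi,
            "hypertension": aht,
            "diabetes": dm,
            **{c: covs[c] for c in covs.columns},
        }
    )
    return Cohort(data=data, provenance=f"synthetic(seed={config.seed})")


def generate_summary_fixtures(out_dir) -> list[Path]:
    """Write the eight published summary tables as CSV files.

    One file per (outcome, sex, scheme), named e.g.
    ``men_aht_cunbae.csv``, with columns ``category, bounds, N, n, cOR,
    aOR`` exactly as published (missing estimates left blank). Case
    totals are verified to be conserved across schemes before writing.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # case-count conservation: the same cases partitioned two ways
    for outcome in (reference_tables.OUTCOME_AHT, reference_tables.OUTCOME_DM):
        for sex in ("male", "female"):
            totals = {
                scheme: sum(r[2] for r in reference_tables.SUMMARY_TABLES[(outcome, sex, scheme)])
                for scheme in ("BMI", "CUNBAE")
            }
            if len(set(totals.values())) != 1:
                raise AssertionError(f"case totals differ across schemes: {outcome}/{sex}")
    paths = []
    for (outcome, sex, scheme), rows in reference_tables.SUMMARY_TABLES.items():
        bounds_key = scheme if scheme == "BMI" else (scheme, sex)
        bounds = reference_tables.CATEGORY_BOUNDS_TEXT[bounds_key]
        df = pd.DataFrame(
            [
                {"category": lab, "bounds": btxt, "N": N, "n": n, "cOR": cor, "aOR": aor}
                for (lab, N, n, cor, aor), btxt in zip(rows, bounds)
            ]
        )
        path = out_dir / f"{_SEX_WORD[sex]}_{outcome}_{scheme.lower()}.csv"
        df.to_csv(path, index=False)
        paths.append(path)
    return paths
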