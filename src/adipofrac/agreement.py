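"""Agreement between the BMI and CUN-BAE obesity classifications.

Because percent body fat depends on sex and age while BMI does not, the
two scales correlate poorly in a pooled two-sex adult sample but very
strongly within sex-and-age strata. This module quantifies that:
Pearson R² between BMI and %BF (overall and per stratum), Cohen's kappa
for the binary obese/not-obese diagnosis with an asymptotic 95% CI,
raw percent agreement, and the obesity prevalence under each scheme
with the CUN-BAE:BMI prevalence ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_AGE_BAND_EDGE = 50.0


class ConstantSeriesError(ValueError):
    """Correlation is undefined for a constant series."""


class DegenerateAgreementError(ValueError):
    """Kappa is undefined when expected agreement is exactly 1."""


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci: tuple[float, float]
    po: float  # observed agreement proportion
    pe: float  # chance-expected agreement proportion
    n: int

    @property
    def percent_agreement(self) -> float:
        return 100.0 * self.po


def pearson_r2(x, y) -> float:
    """Square of the Pearson product-moment correlation.

    Raises ``ConstantSeriesError`` if either series is constant and
    ``ValueError`` for mismatched lengths or n < 3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantSeriesError("correlation undefined for a constant series")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def cohen_kappa(class_a, class_b, *, confidence: float = 0.95) -> KappaResult:
    """Cohen's kappa for two binary classifications of the same subjects.

    κ = (po − pe) / (1 − pe) from the 2×2 cross-classification, with the
    large-sample variance of Fleiss, Cohen & Everitt and a normal-quantile
    confidence interval (1.96·SE at 95%).

    Raises ``DegenerateAgreementError`` when pe = 1 (both classifications
    constant and identical), where kappa is undefined.
    """
    a = np.asarray(class_a).astype(bool)
    b = np.asarray(class_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    n = a.size
    if n == 0:
        raise ValueError("empty series")

    # p[i, j]: proportion classified i by A and j by B (0 = no, 1 = yes)
    p = np.empty((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            p[i, j] = np.mean((a == bool(i)) & (b == bool(j)))
    pa = p.sum(axis=1)  # marginals of A
    pb = p.sum(axis=0)  # marginals of B
    po = float(p[0, 0] + p[1, 1])
    pe = float(pa @ pb)
    if pe == 1.0:
        raise DegenerateAgreementError("expected agreement is 1; kappa undefined")
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss–Cohen–Everitt asymptotic variance of kappa-hat
    term1 = sum(
        p[i, i] * ((1 - pe) - (pa[i] + pb[i]) * (1 - po)) ** 2 for i in (0, 1)
    )
    term2 = (1 - po) ** 2 * sum(
        p[i, j] * (pb[i] + pa[j]) ** 2 for i in (0, 1) for j in (0, 1) if i != j
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + confidence / 2)
    return KappaResult(
        kappa=float(kappa), se=se, ci=(float(kappa - z * se), float(kappa + z * se)),
        po=po, pe=pe, n=int(n),
    )


def _strata(df: pd.DataFrame, age_band_edge: float):
    """Yield (sex, age_band, sub-frame) for all / per-sex / sex×age strata."""
    under = f"<{age_band_edge:g}"
    over = f">={age_band_edge:g}"
    yield "all", "all", df
    for sex in ("male", "female"):
        sdf = df[df["sex"] == sex]
        yield sex, "all", sdf
        yield sex, under, sdf[sdf["age"] < age_band_edge]
        yield sex, over, sdf[sdf["age"] >= age_band_edge]


def prevalence_comparison(
    scored: pd.DataFrame, *, age_band_edge: float = DEFAULT_AGE_BAND_EDGE
) -> pd.DataFrame:
    """Obesity counts and percentages under both schemes, per stratum.

    Returns one row per (sex, age_band) stratum with columns ``n``,
    ``n_obese_bmi``, ``pct_obese_bmi``, ``n_obese_cunbae``,
    ``pct_obese_cunbae`` and ``prevalence_ratio`` (CUN-BAE : BMI).
    Empty strata are omitted.
    """
    rows = []
    for sex, band, sub in _strata(scored, age_band_edge):
        if len(sub) == 0:
            continue
        n = len(sub)
        nb = int(sub["obese_bmi"].sum())
        nc = int(sub["obese_cunbae"].sum())
        rows.append(
            {
                "sex": sex,
                "age_band": band,
                "n": n,
                "n_obese_bmi": nb,
                "pct_obese_bmi": 100.0 * nb / n,
                "n_obese_cunbae": nc,
                "pct_obese_cunbae": 100.0 * nc / n,
                "prevalence_ratio": nc / nb if nb > 0 else np.inf,
            }
        )
    return pd.DataFrame(rows)


def agreement_report(
    scored: pd.DataFrame, *, age_band_edge: float = DEFAULT_AGE_BAND_EDGE
) -> pd.DataFrame:
    """Full scheme-comparison table: one row per stratum.

    Input must be a scored cohort frame (see
    :func:`adipofrac.adiposity.score_cohort`). Columns: stratum keys,
    n, R² between BMI and %BF, obesity counts/percentages under both
    schemes, percent agreement, kappa and its 95% CI.
    """
    rows = []
    for sex, band, sub in _strata(scored, age_band_edge):
        if len(sub) < 3:
            continue
        kr = cohen_kappa(sub["obese_bmi"], sub["obese_cunbae"])
        nb = int(sub["obese_bmi"].sum())
        nc = int(sub["obese_cunbae"].sum())
        n = len(sub)
        rows.append(
            {
                "sex": sex,
                "age_band": band,
                "n": n,
                "r_squared": pearson_r2(sub["bmi"], sub["percent_bf"]),
                "n_obese_bmi": nb,
                "pct_obese_bmi": 100.0 * nb / n,
                "n_obese_cunbae": nc,
                "pct_obese_cunbae": 100.0 * nc / n,
                "percent_agreement": kr.percent_agreement,
                "kappa": kr.kappa,
                "kappa_low": kr.ci[0],
                "kappa_high": kr.ci[1],
            }
        )
    return pd.DataFrame(rows)
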