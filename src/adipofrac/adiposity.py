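"""Body-fat scoring and obesity classification.

Two adiposity schemes are implemented side by side:

* **BMI** — body mass index (kg/m²), with the WHO cut-offs: normal weight
  18.5–24.9, overweight 25–29.9, and three obesity grades at 30, 35 and
  40 kg/m². Obesity is BMI ≥ 30 for both sexes.

* **CUN-BAE** — the Clínica Universidad de Navarra Body Adiposity
  Estimator, a second-order polynomial in BMI, age and sex (coded 0 for
  men, 1 for women) that predicts percent body fat (%BF) in white adults.
  Obesity is %BF ≥ 25 in men and ≥ 35 in women, with 5-point increments
  dividing the five categories.

Both schemes partition their scale into five ordered categories C1–C5;
C1 is always the reference (normal-weight) category. Bounds are half-open
``[lower, upper)`` so that every value maps to exactly one category and
the boundary value 30.0 kg/m² counts as obese.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCHEME_BMI = "BMI"
SCHEME_CUNBAE = "CUNBAE"
CATEGORY_LABELS = ("C1", "C2", "C3", "C4", "C5")

#: BMI category edges, kg/m² (C1 starts at the inclusion floor 18.5).
BMI_EDGES = (18.5, 25.0, 30.0, 35.0, 40.0, np.inf)

#: CUN-BAE %BF category edges per sex.
CUNBAE_EDGES = {
    "male": (-np.inf, 20.0, 25.0, 30.0, 35.0, np.inf),
    "female": (-np.inf, 30.0, 35.0, 40.0, 45.0, np.inf),
}

OBESITY_BMI_CUTOFF = 30.0
OBESITY_BF_CUTOFF = {"male": 25.0, "female": 35.0}

#: Obesity starts at C3 in both schemes (BMI ≥ 30; %BF ≥ 25 men / 35 women).
_OBESE_FROM_INDEX = 2


@dataclass(frozen=True)
class AdiposityCategory:
    """One ordered category of an adiposity scheme."""

    scheme: str
    label: str
    is_obese: bool
    bounds: tuple[float, float]

    @property
    def index(self) -> int:
        return CATEGORY_LABELS.index(self.label)


@dataclass(frozen=True)
class AdiposityScore:
    """BMI and CUN-BAE %BF for one subject."""

    bmi: float
    percent_bf: float
    sex_code: int
    age: float


def _sex_code(sex) -> np.ndarray:
    """Map male/female labels (or 0/1 codes) to the 0/1 coding of the
    body-fat equation: 0 = male, 1 = female."""
    arr = np.asarray(sex)
    if arr.dtype.kind in "ifb":
        code = arr.astype(float)
        if not np.all((code == 0) | (code == 1)):
            raise ValueError("numeric sex must be coded 0 (male) / 1 (female)")
        return code
    mapping = {"male": 0.0, "m": 0.0, "female": 1.0, "f": 1.0}
    try:
        return np.vectorize(lambda s: mapping[str(s).strip().lower()])(arr).astype(float)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"unrecognised sex label: {exc.args[0]!r}") from exc


def cun_bae_percent_bf(age, sex, bmi):
    """Percent body fat from the CUN-BAE equation.

    %BF = -44.988 + 0.503·age + 10.689·sex + 3.172·BMI - 0.026·BMI²
          + 0.181·BMI·sex - 0.02·BMI·age - 0.005·BMI²·sex
          + 0.00021·BMI²·age

    with age in years, BMI in kg/m² and sex coded 0 for men, 1 for women.
    The equation was fit in white adults; no rounding is applied here —
    round only at report time.

    Parameters may be scalars or array-likes (broadcast together).
    Raises ``ValueError`` on non-finite age/BMI.
    """
    s = _sex_code(sex)
    a = np.asarray(age, dtype=float)
    b = np.asarray(bmi, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("age and bmi must be finite")
    b2 = b * b
    bf = (
        -44.988
        + 0.503 * a
        + 10.689 * s
        + 3.172 * b
        - 0.026 * b2
        + 0.181 * b * s
        - 0.02 * b * a
        - 0.005 * b2 * s
        + 0.00021 * b2 * a
    )
    if bf.ndim == 0:
        return float(bf)
    return bf


def classify_bmi(bmi: float) -> AdiposityCategory:
    """Classify a single BMI value into C1–C5.

    Raises ``ValueError`` below the inclusion floor of 18.5 kg/m² —
    underweight subjects must be filtered upstream.
    """
    if not np.isfinite(bmi):
        raise ValueError("bmi must be finite")
    if bmi < BMI_EDGES[0]:
        raise ValueError(f"bmi {bmi} below inclusion floor 18.5 kg/m²")
    idx = int(np.searchsorted(BMI_EDGES[1:-1], bmi, side="right"))
    return AdiposityCategory(
        scheme=SCHEME_BMI,
        label=CATEGORY_LABELS[idx],
        is_obese=idx >= _OBESE_FROM_INDEX,
        bounds=(BMI_EDGES[idx], BMI_EDGES[idx + 1]),
    )


def classify_cunbae(percent_bf: float, sex: str) -> AdiposityCategory:
    """Classify a %BF value into the sex-specific C1–C5 CUN-BAE bands."""
    if not np.isfinite(percent_bf):
        raise ValueError("percent_bf must be finite")
    sex_key = "female" if float(_sex_code(sex)) == 1.0 else "male"
    edges = CUNBAE_EDGES[sex_key]
    idx = int(np.searchsorted(edges[1:-1], percent_bf, side="right"))
    return AdiposityCategory(
        scheme=SCHEME_CUNBAE,
        label=CATEGORY_LABELS[idx],
        is_obese=idx >= _OBESE_FROM_INDEX,
        bounds=(edges[idx], edges[idx + 1]),
    )


def bmi_category_labels(bmi) -> np.ndarray:
    """Vectorised BMI categorisation; returns an array of C1–C5 labels."""
    b = np.asarray(bmi, dtype=float)
    if np.any(b < BMI_EDGES[0]):
        raise ValueError("bmi values below 18.5 kg/m² must be filtered upstream")
    idx = np.searchsorted(BMI_EDGES[1:-1], b, side="right")
    return np.asarray(CATEGORY_LABELS)[idx]


def cunbae_category_labels(percent_bf, sex) -> np.ndarray:
    """Vectorised CUN-BAE categorisation with sex-specific bands."""
    bf = np.atleast_1d(np.asarray(percent_bf, dtype=float))
    code = np.atleast_1d(_sex_code(sex))
    bf, code = np.broadcast_arrays(bf, code)
    idx = np.empty(bf.shape, dtype=int)
    for key, mask in (("male", code == 0.0), ("female", code == 1.0)):
        edges = np.asarray(CUNBAE_EDGES[key][1:-1])
        idx[mask] = np.searchsorted(edges, bf[mask], side="right")
    return np.asarray(CATEGORY_LABELS)[idx]


def score_cohort(data: pd.DataFrame) -> pd.DataFrame:
    """Add adiposity columns to a cohort frame.

    Requires columns ``sex``, ``age``, ``bmi``; returns a copy with
    ``percent_bf``, ``bmi_category``, ``cunbae_category``, ``obese_bmi``
    and ``obese_cunbae`` appended.
    """
    out = data.copy()
    out["percent_bf"] = cun_bae_percent_bf(out["age"], out["sex"], out["bmi"])
    out["bmi_category"] = bmi_category_labels(out["bmi"])
    out["cunbae_category"] = cunbae_category_labels(out["percent_bf"], out["sex"])
    out["obese_bmi"] = out["bmi"] >= OBESITY_BMI_CUTOFF
    cutoff = out["sex"].map(OBESITY_BF_CUTOFF)
    out["obese_cunbae"] = out["percent_bf"] >= cutoff
    return out
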