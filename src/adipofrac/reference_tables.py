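"""Published summary-level category tables for re-analysis.

Transcribed per-category counts and odds ratios from a cross-sectional
survey of 3888 white Spanish adults (2033 men, 1855 women) reporting
previously diagnosed arterial hypertension (AHT) and type 2 diabetes
(DM) by adiposity category under both the BMI and CUN-BAE schemes.
Each entry is one (outcome, sex, scheme) stratum: per category the
number of subjects ``N``, the number of cases ``n``, and the published
crude and adjusted odds ratios against the normal-weight reference
category (``None`` where the source prints no estimate — the sparse
highest-BMI band in men for diabetes).

These tables are the summary-level input mode of the package: crude
odds ratios can be recomputed from (N, n), and attributable fractions
from the case counts and adjusted odds ratios.
"""

from __future__ import annotations

from .adiposity import SCHEME_BMI, SCHEME_CUNBAE

OUTCOME_AHT = "aht"
OUTCOME_DM = "dm"

#: Human-readable category bounds per scheme (women's CUN-BAE bands in
#: parentheses where they differ from men's).
CATEGORY_BOUNDS_TEXT = {
    SCHEME_BMI: ("18.5-24.9", "25-29.9", "30-34.9", "35-39.9", ">=40"),
    (SCHEME_CUNBAE, "male"): ("<=19.9", "20-24.9", "25-29.9", "30-34.9", ">=35"),
    (SCHEME_CUNBAE, "female"): ("<=29.9", "30-34.9", "35-39.9", "40-44.9", ">=45"),
}

#: rows: (category_label, N, n_cases, crude_or, adjusted_or); C1 is the
#: reference with both odds ratios identically 1.
SUMMARY_TABLES: dict[tuple[str, str, str], list[tuple[str, int, int, float | None, float | None]]] = {
    (OUTCOME_AHT, "male", SCHEME_BMI): [
        ("C1", 749, 152, 1.0, 1.0),
        ("C2", 849, 254, 1.68, 1.33),
        ("C3", 328, 169, 4.17, 3.93),
        ("C4", 74, 37, 3.93, 4.50),
        ("C5", 33, 16, 3.70, 8.66),
    ],
    (OUTCOME_AHT, "male", SCHEME_CUNBAE): [
        ("C1", 258, 21, 1.0, 1.0),
        ("C2", 521, 79, 2.02, 1.67),
        ("C3", 631, 208, 5.55, 3.80),
        ("C4", 415, 199, 10.40, 6.80),
        ("C5", 208, 121, 15.70, 11.24),
    ],
    (OUTCOME_AHT, "female", SCHEME_BMI): [
        ("C1", 895, 119, 1.0, 1.0),
        ("C2", 565, 180, 3.05, 1.99),
        ("C3", 259, 110, 4.81, 2.73),
        ("C4", 86, 45, 7.15, 4.93),
        ("C5", 50, 26, 7.06, 7.71),
    ],
    (OUTCOME_AHT, "female", SCHEME_CUNBAE): [
        ("C1", 303, 9, 1.0, 1.0),
        ("C2", 402, 36, 3.21, 2.97),
        ("C3", 464, 108, 9.91, 7.82),
        ("C4", 389, 165, 24.06, 16.10),
        ("C5", 297, 162, 39.20, 23.30),
    ],
    (OUTCOME_DM, "male", SCHEME_BMI): [
        ("C1", 749, 73, 1.0, 1.0),
        ("C2", 849, 113, 1.42, 1.13),
        ("C3", 328, 79, 2.94, 2.37),
        ("C4", 74, 21, 2.97, 3.19),
        ("C5", 33, 5, None, None),
    ],
    (OUTCOME_DM, "male", SCHEME_CUNBAE): [
        ("C1", 258, 9, 1.0, 1.0),
        ("C2", 521, 35, 1.99, 1.66),
        ("C3", 631, 95, 4.90, 3.49),
        ("C4", 415, 87, 7.34, 4.91),
        ("C5", 208, 65, 12.58, 8.34),
    ],
    (OUTCOME_DM, "female", SCHEME_BMI): [
        ("C1", 895, 50, 1.0, 1.0),
        ("C2", 565, 76, 2.63, 1.78),
        ("C3", 259, 45, 3.55, 2.09),
        ("C4", 86, 21, 5.46, 3.44),
        ("C5", 50, 19, 10.36, 8.13),
    ],
    (OUTCOME_DM, "female", SCHEME_CUNBAE): [
        ("C1", 303, 10, 1.0, 1.0),
        ("C2", 402, 23, 1.78, 1.64),
        ("C3", 464, 36, 2.46, 1.86),
        ("C4", 389, 61, 5.45, 3.47),
        ("C5", 297, 81, 10.99, 6.49),
    ],
}

def category_table(outcome: str, sex: str, scheme: str):
    """The summary table for one stratum as a :class:`~adipofrac.risk_models.CategoryTable`."""
    from .risk_models import CategoryRow, CategoryTable

    rows = [
        CategoryRow(label=lab, N=N, n=n)
        for lab, N, n, _, _ in SUMMARY_TABLES[(outcome, sex, scheme)]
    ]
    return CategoryTable(outcome=outcome, sex=sex, scheme=scheme, rows=rows)


def adjusted_or_vector(outcome: str, sex: str, scheme: str) -> list[float | None]:
    """Published adjusted ORs in category order (``None`` where unreported)."""
    return [aor for _, _, _, _, aor in SUMMARY_TABLES[(outcome, sex, scheme)]]


#: Published population attributable fractions (%) per stratum.
PUBLISHED_AFP = {
    (OUTCOME_AHT, "male", SCHEME_BMI): 37.00,
    (OUTCOME_AHT, "male", SCHEME_CUNBAE): 74.03,
    (OUTCOME_AHT, "female", SCHEME_BMI): 45.32,
    (OUTCOME_AHT, "female", SCHEME_CUNBAE): 89.14,
    (OUTCOME_DM, "male", SCHEME_BMI): 26.19,
    (OUTCOME_DM, "male", SCHEME_CUNBAE): 71.54,
    (OUTCOME_DM, "female", SCHEME_BMI): 40.38,
    (OUTCOME_DM, "female", SCHEME_CUNBAE): 65.19,
}
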