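"""Population attributable fraction over exposure categories.

Miettinen's case-load formulation: with exposure levels l = 1..k,
pd_l the share of all cases found at level l (Σ pd_l = 1, reference
level included with OR 1) and OR_l the (adjusted) odds ratio of level
l against the reference,

    AFp = 1 − Σ_l pd_l / OR_l,

expressed as a percentage. The formula accepts odds ratios as the risk
measure, as is customary when outcome prevalence data come from the
same cross-classification. AFp can be computed either from fitted
models or from a published summary table (category, cases, aOR).

A protective exposure pattern can drive AFp below zero; negative values
are returned with a warning, never clamped. AFp is strictly below 100
whenever any cases exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .adiposity import CATEGORY_LABELS
from .risk_models import (
    SCHEME_CATEGORY_COLUMNS,
    CategoryRow,
    CategoryTable,
    build_category_table,
    fit_adjusted_or,
)


class SummaryFormatError(ValueError):
    """A summary CSV violates the category/reference contract."""


@dataclass(frozen=True)
class AFpResult:
    """Attributable fraction with the inputs that produced it."""

    afp: float  # percent
    pd: np.ndarray  # case share per category, sums to 1
    or_vector: np.ndarray  # odds ratio per category, reference = 1
    source: str  # "fitted" | "summary-table"

    @property
    def categories(self) -> int:
        return self.pd.size


def afp_miettinen(case_counts, or_vector, *, source: str = "fitted") -> AFpResult:
    """AFp (%) from case counts and per-category odds ratios.

    ``case_counts[l]`` is the number of cases at exposure level l
    (reference level first, OR 1); ``or_vector[l]`` the matching odds
    ratio. Raises ``ValueError`` on length mismatch, zero total cases
    or any non-positive OR.
    """
    cases = np.asarray(case_counts, dtype=float)
    ors = np.asarray(or_vector, dtype=float)
    if cases.shape != ors.shape or cases.ndim != 1:
        raise ValueError("case_counts and or_vector must be equal-length vectors")
    if np.any(cases < 0):
        raise ValueError("case counts must be non-negative")
    total = cases.sum()
    if total <= 0:
        raise ValueError("no cases: AFp undefined")
    if np.any(~np.isfinite(ors)) or np.any(ors <= 0):
        raise ValueError("all odds ratios must be finite and positive")
    pd_vec = cases / total
    afp = float((1.0 - np.sum(pd_vec / ors)) * 100.0)
    if afp < 0:
        warnings.warn(
            f"negative attributable fraction ({afp:.2f}%): exposure pattern is "
            "protective relative to the reference", stacklevel=2,
        )
    return AFpResult(afp=afp, pd=pd_vec, or_vector=ors, source=source)


def afp_from_estimates(table: CategoryTable, estimates) -> AFpResult:
    """AFp from a category table and its fitted risk estimates.

    Categories with no subjects carry no case mass and are skipped; a
    category that holds cases but lacks a finite odds ratio is an error
    (collapse it first).
    """
    cases, ors = [], []
    for i, (row, est) in enumerate(zip(table.rows, estimates)):
        if est.category_label != row.label:
            raise ValueError("estimates out of order with respect to the table")
        if row.N == 0:
            continue
        orr = 1.0 if i == table.reference_index else est.odds_ratio
        if not np.isfinite(orr):
            raise ValueError(
                f"category {row.label} has {row.n} cases but no usable odds ratio; "
                "collapse sparse categories before computing AFp"
            )
        cases.append(row.n)
        ors.append(orr)
    return afp_miettinen(cases, ors, source="fitted")


def apply_collapse(scored: pd.DataFrame, collapsed: CategoryTable) -> pd.DataFrame:
    """Relabel a scored cohort to a collapsed category set.

    Labels dropped by :func:`collapse_sparse_categories` are mapped to
    the nearest surviving label below them, so regression and AFp run
    on exactly the collapsed partition.
    """
    kept = [r.label for r in collapsed.rows]
    mapping = {}
    current = kept[0]
    for lab in CATEGORY_LABELS:
        if lab in kept:
            current = lab
        mapping[lab] = current
    col = SCHEME_CATEGORY_COLUMNS[collapsed.scheme]
    out = scored.copy()
    out[col] = out[col].map(mapping)
    return out


def fitted_afp(
    scored: pd.DataFrame,
    outcome: str,
    sex: str,
    scheme: str,
    *,
    min_cases: int = 6,
    **fit_kwargs,
) -> AFpResult:
    """End-to-end AFp from a scored cohort.

    Builds the category table, collapses categories with fewer than
    ``min_cases`` cases into their lower neighbour, fits the adjusted
    logistic model on the collapsed partition and applies Miettinen's
    formula to the fitted odds ratios and observed case distribution.
    """
    table = build_category_table(scored, outcome, sex, scheme)
    collapsed = collapse_sparse_categories(table, min_cases=min_cases)
    relabelled = apply_collapse(scored, collapsed)
    estimates = fit_adjusted_or(relabelled, outcome, sex, scheme, **fit_kwargs)
    fit_table = build_category_table(relabelled, outcome, sex, scheme)
    return afp_from_estimates(fit_table, estimates)


def afp_from_summary_csv(path) -> AFpResult:
    """AFp from a summary-level CSV with columns ``category, n, aOR``.

    The first row must be the reference (aOR = 1); category labels must
    be unique. ``N`` and ``cOR`` columns, if present, are ignored here
    but kept for audit by the caller.
    """
    df = pd.read_csv(path)
    required = {"category", "n", "aOR"}
    if not required <= set(df.columns):
        raise SummaryFormatError(f"summary CSV needs columns {sorted(required)}")
    if df["category"].duplicated().any():
        dupes = df.loc[df["category"].duplicated(), "category"].tolist()
        raise SummaryFormatError(f"duplicate categories: {dupes}")
    if df.empty:
        raise SummaryFormatError("empty summary table")
    if not np.isclose(float(df["aOR"].iloc[0]), 1.0):
        raise SummaryFormatError("first row must be the reference with aOR = 1")
    if df["aOR"].isna().any():
        blank = df.loc[df["aOR"].isna(), "category"].tolist()
        raise SummaryFormatError(
            f"categories without an aOR: {blank}; collapse sparse categories first"
        )
    return afp_miettinen(
        df["n"].to_numpy(float), df["aOR"].to_numpy(float), source="summary-table"
    )


def collapse_sparse_categories(table: CategoryTable, min_cases: int = 6) -> CategoryTable:
    """Merge sparse categories into the adjacent lower category.

    Scanning from the top of the ordering, any non-reference category
    with fewer than ``min_cases`` cases has its N and n added to the
    category immediately below; the merge is recorded in the returned
    table's provenance. The reference category is never merged.

    The default of 6 makes a 5-case top band (too sparse for a stable
    OR) fold into its neighbour, mirroring how published analyses leave
    such bands without an estimate.
    """
    rows = list(table.rows)
    prov = list(table.provenance)
    i = len(rows) - 1
    while i > table.reference_index:
        if rows[i].n < min_cases:
            if i - 1 == table.reference_index:
                raise ValueError(
                    f"cannot merge {rows[i].label} into the reference category"
                )
            merged = CategoryRow(
                label=rows[i - 1].label,
                N=rows[i - 1].N + rows[i].N,
                n=rows[i - 1].n + rows[i].n,
            )
            prov.append(f"merged {rows[i].label} (n={rows[i].n}) into {rows[i - 1].label}")
            rows[i - 1 : i + 1] = [merged]
        i -= 1
    return CategoryTable(
        outcome=table.outcome, sex=table.sex, scheme=table.scheme,
        rows=rows, reference_index=table.reference_index, provenance=prov,
    )
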