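"""Category-wise disease risk: contingency tables, crude and adjusted ORs.

For each outcome (hypertension, diabetes), sex and adiposity scheme the
cohort is cross-tabulated into the five ordered categories; category C1
(normal weight / lowest %BF band) is the comparative standard. Risk per
category is expressed as:

* **crude OR** — the closed-form 2×2 odds ratio of each category against
  the reference, with a Woolf (log-odds) 95% confidence interval;
* **adjusted OR** — exponentiated category coefficients of a
  maximum-likelihood logistic regression with the category indicators
  plus education, marital status, tobacco and alcohol use as unordered
  categorical covariates, and additionally age (continuous) when the
  exposure is BMI — the CUN-BAE score already incorporates age, so age
  is deliberately left out of those models. Wald 95% intervals.

A category is flagged non-estimable when it has fewer than 5 cases or
fewer than 5 non-cases; downstream attributable-fraction work collapses
such categories into the adjacent lower band (see
:mod:`adipofrac.attributable_fraction`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .adiposity import CATEGORY_LABELS, SCHEME_BMI, SCHEME_CUNBAE

log = logging.getLogger(__name__)

OUTCOME_COLUMNS = {"aht": "hypertension", "dm": "diabetes"}
SCHEME_CATEGORY_COLUMNS = {SCHEME_BMI: "bmi_category", SCHEME_CUNBAE: "cunbae_category"}
BASE_COVARIATES = ("education", "marital", "tobacco", "alcohol")

#: Minimum cases and non-cases for a category OR to be considered stable.
MIN_CELL = 5

_Z95 = 1.959963984540054


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect separation) for some category."""


class ConvergenceError(RuntimeError):
    """IRLS failed to converge within the iteration budget."""


@dataclass(frozen=True)
class CategoryRow:
    label: str
    N: int  # subjects in the category
    n: int  # cases in the category


@dataclass
class CategoryTable:
    """Per-category totals and case counts for one outcome/sex/scheme."""

    outcome: str
    sex: str
    scheme: str
    rows: list[CategoryRow]
    reference_index: int = 0
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        for r in self.rows:
            if not 0 <= r.n <= r.N:
                raise ValueError(f"invalid counts in row {r.label}: n={r.n}, N={r.N}")

    @property
    def total_subjects(self) -> int:
        return sum(r.N for r in self.rows)

    @property
    def total_cases(self) -> int:
        return sum(r.n for r in self.rows)

    def case_counts(self) -> np.ndarray:
        return np.array([r.n for r in self.rows], dtype=float)


@dataclass(frozen=True)
class RiskEstimate:
    """Odds ratio (crude or adjusted) with 95% CI for one category."""

    category_label: str
    estimate_type: str  # "crude" | "adjusted"
    odds_ratio: float
    ci95: tuple[float, float] | None
    prevalence: float | None = None
    estimable: bool = True


def build_category_table(
    scored: pd.DataFrame, outcome: str, sex: str, scheme: str
) -> CategoryTable:
    """Cross-tabulate a scored cohort into a :class:`CategoryTable`.

    Categories appear in scheme order (reference C1 first); empty
    categories are retained with N = 0 and recorded in the table's
    provenance.
    """
    ycol = OUTCOME_COLUMNS[outcome]
    ccol = SCHEME_CATEGORY_COLUMNS[scheme]
    sub = scored[scored["sex"] == sex]
    rows, prov = [], []
    for label in CATEGORY_LABELS:
        grp = sub[sub[ccol] == label]
        N = len(grp)
        n = int(grp[ycol].astype(bool).sum())
        if N == 0:
            prov.append(f"empty category {label}")
        rows.append(CategoryRow(label=label, N=N, n=n))
    return CategoryTable(outcome=outcome, sex=sex, scheme=scheme, rows=rows, provenance=prov)


def crude_odds_ratio(
    exposed: tuple[int, int],
    reference: tuple[int, int],
    *,
    label: str = "exposed",
    continuity: bool = False,
) -> RiskEstimate:
    """Closed-form odds ratio of an exposure category against the reference.

    ``exposed`` and ``reference`` are (N subjects, n cases) pairs. The
    95% CI is Woolf's log-odds interval,
    exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).

    With a zero cell the OR is non-estimable; pass ``continuity=True``
    to apply the Haldane–Anscombe 0.5 correction to all four cells
    instead of flagging.
    """
    (N_e, n_e), (N_r, n_r) = exposed, reference
    a, b = float(n_e), float(N_e - n_e)  # exposed: cases, non-cases
    c, d = float(n_r), float(N_r - n_r)  # reference: cases, non-cases
    if min(a, b, c, d) < 0:
        raise ValueError("counts must satisfy 0 <= n <= N")
    if min(a, b, c, d) == 0:
        if not continuity:
            return RiskEstimate(
                category_label=label, estimate_type="crude",
                odds_ratio=float("nan"), ci95=None,
                prevalence=100.0 * n_e / N_e if N_e else None, estimable=False,
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(orr) - _Z95 * se), np.exp(np.log(orr) + _Z95 * se)
    return RiskEstimate(
        category_label=label, estimate_type="crude", odds_ratio=float(orr),
        ci95=(float(lo), float(hi)), prevalence=100.0 * n_e / N_e if N_e else None,
    )


def crude_or_table(table: CategoryTable, **kwargs) -> list[RiskEstimate]:
    """Crude OR per category against the table's reference row.

    The reference itself is reported with OR 1 and no CI.
    """
    ref = table.rows[table.reference_index]
    out = []
    for i, row in enumerate(table.rows):
        if i == table.reference_index:
            out.append(
                RiskEstimate(
                    category_label=row.label, estimate_type="crude", odds_ratio=1.0,
                    ci95=None, prevalence=100.0 * row.n / row.N if row.N else None,
                )
            )
        else:
            out.append(
                crude_odds_ratio((row.N, row.n), (ref.N, ref.n), label=row.label, **kwargs)
            )
    return out


def _design_matrix(
    sub: pd.DataFrame, ycol: str, ccol: str, covariates: tuple[str, ...]
) -> tuple[pd.Series, pd.DataFrame, dict[str, str]]:
    y = sub[ycol].astype(float)
    X = pd.DataFrame(index=sub.index)
    cat_cols = {}
    present = set(sub[ccol].unique())
    for lab in CATEGORY_LABELS[1:]:
        if lab not in present:  # empty category: no indicator, no estimate
            continue
        col = f"{ccol}[{lab}]"
        X[col] = (sub[ccol] == lab).astype(float)
        cat_cols[lab] = col
    for cov in covariates:
        if cov == "age":
            X["age"] = sub["age"].astype(float)
            continue
        levels = sub[cov].value_counts()  # most frequent level is reference
        for lev in levels.index[1:]:
            X[f"{cov}[{lev}]"] = (sub[cov] == lev).astype(float)
    X = sm.add_constant(X, prepend=True)
    return y, X, cat_cols


def fit_adjusted_or(
    scored: pd.DataFrame,
    outcome: str,
    sex: str,
    scheme: str,
    covariates: tuple[str, ...] | None = None,
    *,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> list[RiskEstimate]:
    """Adjusted ORs per category from a logistic regression.

    The default covariate set is education, marital status, tobacco and
    alcohol use, plus continuous age if and only if the scheme is BMI.
    Complete-case rows only (dropped counts are logged). Returns one
    :class:`RiskEstimate` per category, the reference with OR 1.

    Raises :class:`SeparationError` on perfect separation and
    :class:`ConvergenceError` if the likelihood does not converge.
    """
    if covariates is None:
        covariates = BASE_COVARIATES + (("age",) if scheme == SCHEME_BMI else ())
    ycol = OUTCOME_COLUMNS[outcome]
    ccol = SCHEME_CATEGORY_COLUMNS[scheme]
    needed = [ycol, ccol] + [c for c in covariates]
    sub = scored[scored["sex"] == sex]
    complete = sub.dropna(subset=needed)
    if len(complete) < len(sub):
        log.info(
            "complete-case deletion dropped %d of %d rows (%s/%s/%s)",
            len(sub) - len(complete), len(sub), outcome, sex, scheme,
        )
    y, X, cat_cols = _design_matrix(complete, ycol, ccol, covariates)
    n_params = X.shape[1]
    if len(complete) < 10 * n_params:
        warnings.warn(
            f"only {len(complete)} complete cases for {n_params} parameters; "
            "estimates may be unstable", stacklevel=2,
        )
    if y.nunique() < 2:
        raise SeparationError("outcome is constant; model degenerate")

    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
        except (np.linalg.LinAlgError, RuntimeWarning, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError(
            f"no convergence in {maxiter} iterations; ||grad|| at exit: "
            f"{np.abs(res.model.score(res.params)).max():.3g}"
        )
    if np.abs(res.params).max() > 30:
        worst = res.params.abs().idxmax()
        raise SeparationError(f"quasi-separation detected for term {worst!r}")

    table = build_category_table(scored, outcome, sex, scheme)
    by_label = {r.label: r for r in table.rows}
    out = [
        RiskEstimate(
            category_label=CATEGORY_LABELS[0], estimate_type="adjusted",
            odds_ratio=1.0, ci95=None,
            prevalence=(100.0 * by_label["C1"].n / by_label["C1"].N)
            if by_label["C1"].N else None,
        )
    ]
    conf = res.conf_int(alpha=0.05)
    for lab in CATEGORY_LABELS[1:]:
        row = by_label[lab]
        if lab not in cat_cols:
            out.append(
                RiskEstimate(
                    category_label=lab, estimate_type="adjusted",
                    odds_ratio=float("nan"), ci95=None, prevalence=None,
                    estimable=False,
                )
            )
            continue
        col = cat_cols[lab]
        estimable = min(row.n, row.N - row.n) >= MIN_CELL
        out.append(
            RiskEstimate(
                category_label=lab, estimate_type="adjusted",
                odds_ratio=float(np.exp(res.params[col])),
                ci95=(float(np.exp(conf.loc[col, 0])), float(np.exp(conf.loc[col, 1]))),
                prevalence=100.0 * row.n / row.N if row.N else None,
                estimable=estimable,
            )
        )
    return out


def risk_table(
    scored: pd.DataFrame, outcome: str, sex: str, scheme: str, **fit_kwargs
) -> pd.DataFrame:
    """Summary-table view: category, N, n, prevalence, cOR, aOR with CIs."""
    table = build_category_table(scored, outcome, sex, scheme)
    crude = crude_or_table(table)
    adjusted = fit_adjusted_or(scored, outcome, sex, scheme, **fit_kwargs)
    rows = []
    for row, c, a in zip(table.rows, crude, adjusted):
        rows.append(
            {
                "category": row.label,
                "N": row.N,
                "n": row.n,
                "prevalence": 100.0 * row.n / row.N if row.N else np.nan,
                "cOR": c.odds_ratio,
                "cOR_low": c.ci95[0] if c.ci95 else np.nan,
                "cOR_high": c.ci95[1] if c.ci95 else np.nan,
                "aOR": a.odds_ratio,
                "aOR_low": a.ci95[0] if a.ci95 else np.nan,
                "aOR_high": a.ci95[1] if a.ci95 else np.nan,
                "estimable": c.estimable and a.estimable,
            }
        )
    return pd.DataFrame(rows)


def simulate_woolf_coverage(
    true_or: float,
    n_per_arm: int,
    p_reference: float,
    n_replicates: int,
    seed: int,
) -> float:
    """Empirical coverage of the Woolf 95% CI in seeded 2×2 simulations.

    Draws case counts binomially in a reference arm with case probability
    ``p_reference`` and an exposed arm whose odds are ``true_or`` times
    larger, and returns the fraction of replicates whose Woolf interval
    contains ``true_or`` (non-estimable replicates are excluded).
    """
    rng = np.random.default_rng(seed)
    odds_e = true_or * p_reference / (1 - p_reference)
    p_e = odds_e / (1 + odds_e)
    hits = total = 0
    for _ in range(n_replicates):
        n_r = int(rng.binomial(n_per_arm, p_reference))
        n_e = int(rng.binomial(n_per_arm, p_e))
        est = crude_odds_ratio((n_per_arm, n_e), (n_per_arm, n_r))
        if not est.estimable:
            continue
        total += 1
        if est.ci95[0] <= true_or <= est.ci95[1]:
            hits += 1
    if total == 0:
        raise RuntimeError("no estimable replicates")
    return hits / total
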