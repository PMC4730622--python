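"""Contingency tables, crude odds ratios and the logistic adjusted ORs."""

import numpy as np
import pandas as pd
import pytest

from adipofrac import risk_models
from adipofrac.risk_models import (
    SeparationError,
    build_category_table,
    crude_odds_ratio,
    crude_or_table,
    fit_adjusted_or,
    simulate_woolf_coverage,
)


class TestCrudeOddsRatio:
    @pytest.mark.parametrize(
        "exposed, reference, expected",
        [
            ((849, 254), (749, 152), 1.68),  # overweight men vs normal weight
            ((297, 162), (303, 9), 39.20),  # women in the top %BF band
            ((749, 152), (749, 152), 1.0),
        ],
    )
    def test_published_and_identity_values(self, exposed, reference, expected):
        est = crude_odds_ratio(exposed, reference)
        assert est.odds_ratio == pytest.approx(expected, abs=0.005)

    def test_woolf_interval_brackets_and_matches_statsmodels(self):
        import statsmodels.api as sm

        est = crude_odds_ratio((849, 254), (749, 152))
        lo, hi = est.ci95
        assert lo < est.odds_ratio < hi
        t22 = sm.stats.Table2x2(np.array([[254, 849 - 254], [152, 749 - 152]]))
        assert est.odds_ratio == pytest.approx(t22.oddsratio)
        assert lo == pytest.approx(t22.oddsratio_confint()[0])
        assert hi == pytest.approx(t22.oddsratio_confint()[1])

    def test_zero_cell_flagged_unless_continuity(self):
        flagged = crude_odds_ratio((10, 0), (20, 5))
        assert not flagged.estimable and np.isnan(flagged.odds_ratio)
        corrected = crude_odds_ratio((10, 0), (20, 5), continuity=True)
        assert corrected.estimable and corrected.odds_ratio > 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            crude_odds_ratio((10, 12), (20, 5))

    def test_woolf_coverage_near_nominal(self):
        """Empirical 95% CI coverage in seeded 2x2 simulations."""
        cov = simulate_woolf_coverage(
            true_or=2.0, n_per_arm=200, p_reference=0.2, n_replicates=1000, seed=2024
        )
        assert cov == pytest.approx(0.95, abs=0.03)


class TestCategoryTable:
    def test_reference_first_and_counts_consistent(self, scored):
        table = build_category_table(scored, "aht", "male", "CUNBAE")
        assert [r.label for r in table.rows] == ["C1", "C2", "C3", "C4", "C5"]
        men = scored[scored.sex == "male"]
        assert table.total_subjects == len(men)
        assert table.total_cases == int(men["hypertension"].sum())

    @pytest.mark.parametrize("outcome", ["aht", "dm"])
    @pytest.mark.parametrize("sex", ["male", "female"])
    def test_case_count_conservation_across_schemes(self, scored, outcome, sex):
        """The same cases are partitioned twice, so totals must agree."""
        t_bmi = build_category_table(scored, outcome, sex, "BMI")
        t_cun = build_category_table(scored, outcome, sex, "CUNBAE")
        assert t_bmi.total_cases == t_cun.total_cases
        assert t_bmi.total_subjects == t_cun.total_subjects

    def test_empty_categories_retained_and_flagged(self):
        df = pd.DataFrame(
            {
                "sex": ["male"] * 10,
                "hypertension": [True] * 2 + [False] * 8,
                "cunbae_category": ["C1"] * 10,
            }
        )
        table = build_category_table(df, "aht", "male", "CUNBAE")
        assert [(r.label, r.N, r.n) for r in table.rows] == [
            ("C1", 10, 2), ("C2", 0, 0), ("C3", 0, 0), ("C4", 0, 0), ("C5", 0, 0)
        ]
        assert len(table.provenance) == 4

    def test_crude_or_table_reference_row(self, scored):
        table = build_category_table(scored, "aht", "female", "BMI")
        ests = crude_or_table(table)
        assert ests[0].odds_ratio == 1.0 and ests[0].ci95 is None


def _two_by_two_frame(n_e, a, n_r, c):
    """Subject-level frame for an exposed/reference 2x2 table."""
    return pd.DataFrame(
        {
            "sex": "male",
            "hypertension": [True] * a + [False] * (n_e - a) + [True] * c + [False] * (n_r - c),
            "cunbae_category": ["C2"] * n_e + ["C1"] * n_r,
        }
    )


class TestAdjustedOR:
    def test_logistic_reproduces_closed_form_on_two_by_two(self):
        """Saturated-model identity: a logistic fit on a single binary
        exposure equals the contingency-table odds ratio."""
        df = _two_by_two_frame(140, 37, 160, 22)
        ests = fit_adjusted_or(df, "aht", "male", "CUNBAE", covariates=())
        closed = crude_odds_ratio((140, 37), (160, 22))
        fitted = next(e for e in ests if e.category_label == "C2")
        assert fitted.odds_ratio == pytest.approx(closed.odds_ratio, rel=1e-6)

    def test_constant_outcome_raises(self):
        df = _two_by_two_frame(50, 0, 50, 0)
        df["hypertension"] = False
        with pytest.raises(SeparationError):
            fit_adjusted_or(df, "aht", "male", "CUNBAE", covariates=())

    def test_perfect_separation_raises(self):
        df = _two_by_two_frame(50, 50, 50, 0)
        with pytest.raises(SeparationError):
            fit_adjusted_or(df, "aht", "male", "CUNBAE", covariates=())

    def test_age_enters_bmi_models_only(self, scored):
        """Age must be adjusted for alongside BMI but not with CUN-BAE,
        which already encodes it: the default BMI design is the base
        covariates plus age, the default CUN-BAE design is without it."""
        covs = risk_models.BASE_COVARIATES
        default_bmi = fit_adjusted_or(scored, "aht", "male", "BMI")
        with_age = fit_adjusted_or(scored, "aht", "male", "BMI", covariates=covs + ("age",))
        without_age = fit_adjusted_or(scored, "aht", "male", "BMI", covariates=covs)
        assert default_bmi[2].odds_ratio == pytest.approx(with_age[2].odds_ratio, rel=1e-12)
        assert default_bmi[2].odds_ratio != pytest.approx(without_age[2].odds_ratio, rel=1e-6)
        default_cun = fit_adjusted_or(scored, "aht", "male", "CUNBAE")
        no_age_cun = fit_adjusted_or(scored, "aht", "male", "CUNBAE", covariates=covs)
        assert default_cun[2].odds_ratio == pytest.approx(no_age_cun[2].odds_ratio, rel=1e-12)

    def test_monotone_gradient_on_default_cohort(self, scored):
        """Outcome risk rises with %BF by construction, so fitted aORs
        should increase across CUN-BAE categories."""
        for sex in ("male", "female"):
            ests = fit_adjusted_or(scored, "aht", sex, "CUNBAE")
            ors = [e.odds_ratio for e in ests]
            assert all(b > a for a, b in zip(ors, ors[1:])), (sex, ors)

    def test_sparse_category_flagged_non_estimable(self):
        rng = np.random.default_rng(3)
        n = 400
        df = pd.DataFrame(
            {
                "sex": "male",
                "hypertension": rng.random(n) < 0.3,
                "cunbae_category": ["C1"] * 200 + ["C2"] * 196 + ["C3"] * 4,
            }
        )
        df.loc[df.index[-4:], "hypertension"] = [True, True, False, False]
        ests = fit_adjusted_or(df, "aht", "male", "CUNBAE", covariates=())
        assert not next(e for e in ests if e.category_label == "C3").estimable

    def test_risk_table_shape(self, scored):
        table = risk_models.risk_table(scored, "dm", "female", "CUNBAE")
        assert list(table["category"]) == ["C1", "C2", "C3", "C4", "C5"]
        assert {"N", "n", "prevalence", "cOR", "aOR", "aOR_low", "aOR_high"} <= set(table.columns)
        assert table["n"].sum() == int(scored[scored.sex == "female"]["diabetes"].sum())
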