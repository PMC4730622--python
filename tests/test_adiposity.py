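"""Body-fat equation and category classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipofrac import adiposity
from adipofrac.adiposity import (
    CATEGORY_LABELS,
    classify_bmi,
    classify_cunbae,
    cun_bae_percent_bf,
)


class TestBodyFatEquation:
    @pytest.mark.parametrize(
        "age, sex, bmi, expected",
        [
            (40, "male", 25.0, 23.43),  # hand evaluation, term by term
            (40, "female", 25.0, 35.52),  # male value + sex terms at BMI 25
            (50, "male", 30.0, 31.37),
        ],
    )
    def test_hand_derived_values(self, age, sex, bmi, expected):
        assert cun_bae_percent_bf(age, sex, bmi) == pytest.approx(expected, abs=0.01)

    def test_sex_gap_is_age_independent(self):
        """female - male %BF at fixed BMI is 10.689 + 0.181·BMI - 0.005·BMI²."""
        for bmi in (18.5, 25.0, 40.0, 60.0):
            gaps = [
                cun_bae_percent_bf(age, "female", bmi) - cun_bae_percent_bf(age, "male", bmi)
                for age in (18, 47, 93)
            ]
            expected = 10.689 + 0.181 * bmi - 0.005 * bmi**2
            assert np.allclose(gaps, expected, atol=1e-12)

    def test_vectorised_matches_scalar(self):
        ages = np.array([20.0, 50.0, 80.0])
        bmis = np.array([19.0, 27.0, 44.0])
        vec = cun_bae_percent_bf(ages, ["male", "female", "male"], bmis)
        scalars = [
            cun_bae_percent_bf(a, s, b)
            for a, s, b in zip(ages, ["male", "female", "male"], bmis)
        ]
        assert np.allclose(vec, scalars)

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            cun_bae_percent_bf(np.nan, "male", 25.0)
        with pytest.raises(ValueError):
            cun_bae_percent_bf(40, "male", np.inf)

    def test_monotone_in_age_and_sex_gap_on_grid(self):
        """On age 18-100 × BMI 18.5-60 (step 0.1): %BF strictly increases
        with age for both sexes, and women exceed men everywhere."""
        ages = np.arange(18, 101, dtype=float)
        bmis = np.arange(18.5, 60.05, 0.1)
        aa, bb = np.meshgrid(ages, bmis, indexing="ij")
        for sex in ("male", "female"):
            bf = cun_bae_percent_bf(aa, sex, bb)
            assert np.all(np.diff(bf, axis=0) > 0), f"not monotone in age ({sex})"
        gap = cun_bae_percent_bf(aa, "female", bb) - cun_bae_percent_bf(aa, "male", bb)
        assert np.all(gap > 0)

    def test_monotone_in_bmi_where_the_quadratic_allows(self):
        """%BF rises with BMI throughout the grid for men. For women the
        quadratic BMI terms turn the derivative negative at extreme BMI in
        the young (roughly BMI > 55 under age ~70) — a real feature of the
        equation — so strict monotonicity is asserted only up to BMI 50,
        a range covering virtually all of the target population."""
        ages = np.arange(18, 101, dtype=float)
        bmis = np.arange(18.5, 60.05, 0.1)
        aa, bb = np.meshgrid(ages, bmis, indexing="ij")
        assert np.all(np.diff(cun_bae_percent_bf(aa, "male", bb), axis=1) > 0)
        women = cun_bae_percent_bf(aa, "female", bb)
        in_range = bb[:, 1:] <= 50.0
        assert np.all(np.diff(women, axis=1)[in_range] > 0)
        # and the non-monotone corner really exists
        assert cun_bae_percent_bf(18, "female", 60.0) < cun_bae_percent_bf(18, "female", 55.0)


class TestClassification:
    @pytest.mark.parametrize(
        "bmi, label, obese",
        [
            (26.9, "C2", False),  # the male cohort mean lands in overweight
            (30.0, "C3", True),  # boundary is obese: "30 or more"
            (18.5, "C1", False),
            (39.99, "C4", True),
            (40.0, "C5", True),
        ],
    )
    def test_bmi_categories(self, bmi, label, obese):
        cat = classify_bmi(bmi)
        assert (cat.label, cat.is_obese) == (label, obese)
        assert cat.bounds[0] <= bmi < cat.bounds[1]

    @pytest.mark.parametrize(
        "bf, sex, label, obese",
        [
            (27.1, "male", "C3", True),  # male cohort mean %BF is already obese
            (37.6, "female", "C3", True),
            (24.999, "male", "C2", False),
            (34.999, "female", "C2", False),
            (12.0, "male", "C1", False),  # below the nominal C1 floor: still C1
            (45.0, "female", "C5", True),
        ],
    )
    def test_cunbae_categories(self, bf, sex, label, obese):
        cat = classify_cunbae(bf, sex)
        assert (cat.label, cat.is_obese) == (label, obese)

    def test_bmi_below_floor_rejected(self):
        with pytest.raises(ValueError):
            classify_bmi(17.9)

    @settings(derandomize=True, max_examples=200)
    @given(
        value=st.floats(min_value=-10, max_value=90, allow_nan=False),
        sex=st.sampled_from(["male", "female"]),
    )
    def test_classification_total_and_exclusive(self, value, sex):
        """Every (%BF, sex) maps to exactly one category whose bounds
        contain the value; obesity coincides with category >= C3."""
        cat = classify_cunbae(value, sex)
        assert cat.label in CATEGORY_LABELS
        assert cat.bounds[0] <= value < cat.bounds[1]
        assert cat.is_obese == (cat.index >= 2)

    def test_vector_labels_match_scalar(self):
        rng = np.random.default_rng(0)
        bmis = rng.uniform(18.5, 55, 200)
        assert all(
            lab == classify_bmi(b).label
            for lab, b in zip(adiposity.bmi_category_labels(bmis), bmis)
        )
        bfs = rng.uniform(5, 60, 200)
        sexes = rng.choice(["male", "female"], 200)
        assert all(
            lab == classify_cunbae(bf, s).label
            for lab, bf, s in zip(adiposity.cunbae_category_labels(bfs, sexes), bfs, sexes)
        )


def test_score_cohort_adds_consistent_columns(scored):
    assert {"percent_bf", "bmi_category", "cunbae_category", "obese_bmi", "obese_cunbae"} <= set(
        scored.columns
    )
    # flags agree with the categorical encoding
    assert (scored["obese_bmi"] == (scored["bmi"] >= 30.0)).all()
    recomputed = scored["cunbae_category"].isin(["C3", "C4", "C5"])
    assert (scored["obese_cunbae"] == recomputed).all()
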