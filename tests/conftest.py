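import pandas as pd
import pytest

from adipofrac import adiposity, synthetic_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (n=3888, seed 1)."""
    return synthetic_cohort.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def scored(default_cohort):
    return adiposity.score_cohort(default_cohort.data)


@pytest.fixture()
def tiny_cohort_csv(tmp_path):
    """A 10-row valid cohort file with canonical column names."""
    df = pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(10)],
            "sex": ["male", "female"] * 5,
            "age": [25, 34, 45, 52, 61, 38, 47, 70, 29, 55],
            "bmi": [22.0, 24.5, 27.3, 31.0, 29.9, 19.2, 35.4, 26.0, 41.2, 23.3],
            "hypertension": [0, 0, 1, 1, 0, 0, 1, 1, 0, 0],
            "diabetes": [0, 0, 0, 1, 0, 0, 1, 0, 0, 0],
            "education": ["primary", "secondary"] * 5,
            "marital": ["married", "single"] * 5,
            "tobacco": ["never", "current"] * 5,
            "alcohol": ["none", "moderate"] * 5,
        }
    )
    path = tmp_path / "cohort.csv"
    df.to_csv(path, index=False)
    return path
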