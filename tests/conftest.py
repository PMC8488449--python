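import numpy as np
import pandas as pd
import pytest

from obesim.cohort import CohortParams, IntakeModel, generate_cohort
from obesim.growth import load_default_ears, load_toy_lms


@pytest.fixture(scope="session")
def lms_ref():
    return load_toy_lms()


@pytest.fixture(scope="session")
def ear_table():
    return load_default_ears()


@pytest.fixture(scope="session")
def default_cohort_small():
    """Default generator, n=3000 — cheap fixture for plumbing tests."""
    return generate_cohort(CohortParams(n_children=3000, seed=11))


@pytest.fixture(scope="session")
def cohort_20k():
    """Default generator at n=20000 with intermediate-confounder effects on
    intake switched on, so mediator weights are non-trivial."""
    params = CohortParams(
        n_children=20000,
        seed=7,
        intake_model=IntakeModel(
            confounder_effects={"tv_high": 0.04, "activity_low": 0.03, "birthweight_high": 0.02}
        ),
    )
    return generate_cohort(params)


def toy_cohort(
    intakes,
    sexes=None,
    educations=None,
    obese_6y=None,
    seed=0,
) -> pd.DataFrame:
    """Hand-built minimal cohort frame for row-level oracles."""
    n = len(intakes)
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": sexes if sexes is not None else ["male"] * n,
            "ethnicity": ["white"] * n,
            "education": educations if educations is not None else ["mid"] * n,
            "birthweight_cat": ["mid"] * n,
            "health": ["good"] * n,
            "activity_cat": ["mid"] * n,
            "tv_cat": ["mid"] * n,
            "imd_score": rng.standard_normal(n),
            "imd_quintile": 3,
            "intake_kcal": np.asarray(intakes, dtype=float),
            "bmi_z_3y": 0.0,
            "obese_3y": False,
            "bmi_z_6y": 0.0,
            "obese_6y": obese_6y if obese_6y is not None else [False] * n,
        }
    )
    return df.astype({"obese_3y": "boolean", "obese_6y": "boolean"})
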