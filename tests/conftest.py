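import numpy as np
import pandas as pd
import pytest

from diabetes_typology.simulate import gen_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Mixed diabetic/non-diabetic biomarker cohort with truth labels."""
    return gen_cohort(n_diabetic=600, n_nondiabetic=400, seed=42)


@pytest.fixture(scope="session")
def diabetic_cohort() -> pd.DataFrame:
    """Diabetics only, no insulin users: every record pipeline-eligible."""
    return gen_cohort(n_diabetic=800, insulin_user_fraction=0.0, seed=7)
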