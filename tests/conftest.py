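import numpy as np
import pandas as pd
import pytest

from akiplanner import CohortConfig, generate_cohort, run_pipeline
from akiplanner.config import PLAN_PARAMS, PREOP_FEATURES


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """The default 998-patient synthetic cohort (seed 7)."""
    return generate_cohort(CohortConfig())


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default pipeline run shared across tests."""
    return run_pipeline()


@pytest.fixture(scope="session")
def linear_fixture():
    """Noiseless linear map from 8 features to 6 neutral targets."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(500, 8))
    A = rng.normal(size=(8, 6))
    b = rng.normal(size=6)
    params = [f"y{i}" for i in range(6)]
    df = pd.DataFrame(np.hstack([X, X @ A + b]), columns=PREOP_FEATURES + params)
    return df, params


@pytest.fixture()
def plan_frame():
    """Helper: wrap a plan matrix into a DataFrame with canonical columns."""

    def make(X: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(np.asarray(X, dtype=float), columns=PLAN_PARAMS)

    return make
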