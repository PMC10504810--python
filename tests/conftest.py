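import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import sensetraits as st
from sensetraits.instruments import SENSORY_SUBSCALES

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

#: the covariate set of the 13-predictor stability design (man dummy only)
COVARIATES_13 = ["age", "adhd", "dcd", "anxiety", "mood", "gender_man"]


def scored_design(seed: int = 1, outcome: str = "aloof", covariates=COVARIATES_13):
    """Generate a default cohort, score it, and return the (X, y) design
    of modality subscale scores plus covariates."""
    table, cov, truth = st.generate_dataset(st.SimConfig(seed=seed))
    key = st.drop_overlap_items(table.key)
    scores = st.score_subscales(table.responses, key)
    X = pd.DataFrame({s: scores[s].to_numpy(dtype=float) for s in SENSORY_SUBSCALES})
    for c in covariates:
        X[c] = cov[c].to_numpy(dtype=float)
    y = scores[outcome].to_numpy(dtype=float)
    return X, y, scores, cov, truth


@pytest.fixture(scope="session")
def default_cohort():
    table, cov, truth = st.generate_dataset(st.SimConfig(seed=1))
    return table, cov, truth


@pytest.fixture(scope="session")
def default_design():
    return scored_design(seed=1)


@pytest.fixture(scope="session")
def standardized_design(default_design):
    X, y, *_ = default_design
    Xs, ys, params = st.standardize_design(X, y)
    return pd.DataFrame(Xs, columns=X.columns), ys, params
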