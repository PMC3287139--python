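import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import chemomir as cm

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted_survival_cohort():
    """Small survival cohort with a recoverable planted hazard signature."""
    cfg = cm.SimulationConfig(n_cancer=82, n_features=120, n_diff_features=0,
                              n_hazard_features=5, hazard_log_effect=1.0, seed=42)
    return cm.generate_survival_cohort(cfg)


@pytest.fixture(scope="session")
def planted_survival_data(planted_survival_cohort):
    co = planted_survival_cohort
    X = co.mirna_expression()
    t = co.survival["ttp_months"].to_numpy()
    e = co.survival["event"].to_numpy().astype(bool)
    return X, t, e


@pytest.fixture(scope="session")
def fitted_risk_model(planted_survival_data):
    X, t, e = planted_survival_data
    return cm.fit_risk_model(X, t, e, selection_alpha=0.05)


@pytest.fixture()
def toy_expression():
    return pd.DataFrame(
        [[0.5, -1.25], [2.0, 0.0]],
        index=pd.Index(["miR-a", "miR-b"], name="feature_id"),
        columns=["s1", "s2"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
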