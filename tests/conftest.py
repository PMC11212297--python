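import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_cohort():
    """Ten hand-built visits, both arms, known proportions and means."""
    return pd.DataFrame(
        {
            "arm": ["rural"] * 4 + ["referral"] * 6,
            "comorbidity_level": [0, 1, 2, 0, 0, 1, 3, 4, 2, 0],
            "event": [1, 0, 0, 0, 1, 1, 0, 0, 0, 1],
            "age": [40.0, 50.0, 60.0, 70.0, 30.0, 35.0, 45.0, 55.0, 65.0, 75.0],
            "sex_female": [1, 0, 1, 0, 1, 1, 0, 0, 1, 0],
        }
    )


@pytest.fixture
def separation_xy():
    """Complete separation: x perfectly predicts y."""
    y = np.array([0.0, 0.0, 1.0, 1.0])
    x = np.array([0.0, 0.0, 1.0, 1.0])
    return y, x


@pytest.fixture
def separation_cohort(separation_xy):
    y, x = separation_xy
    return pd.DataFrame({"event": y.astype(int), "x": x})
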