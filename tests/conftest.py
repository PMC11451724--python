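import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Small default-parameter simulated dataset (64 strata, 20 flies/cell)."""
    from drlifespan import simulate_dataset

    return simulate_dataset(seed=7, flies_per_cell=20)


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale default dataset (16,000 flies)."""
    from drlifespan import simulate_dataset

    return simulate_dataset(seed=11)


def make_survival_frame(time, event, **covariates) -> pd.DataFrame:
    df = pd.DataFrame({"time_days": np.asarray(time, dtype=float),
                       "event": np.asarray(event, dtype=int)})
    for name, values in covariates.items():
        df[name] = values
    return df
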