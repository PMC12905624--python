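import warnings

import numpy as np
import pandas as pd
import pytest

import glycomood as g


def make_series(values, start="2024-01-01 00:00", step_min=5, sensor="S1"):
    """Regularly sampled glucose table used across preprocessing tests."""
    values = np.asarray(values, dtype=float)
    ts = pd.date_range(start, periods=len(values), freq=f"{step_min}min")
    return pd.DataFrame({"timestamp": ts, "glucose_mg_dl": values,
                         "sensor_id": sensor})


@pytest.fixture(scope="session")
def small_cohort():
    """Small but full-featured cohort: traces, EMA, labs, ground truth."""
    params = g.CohortParams(n_participants=6, n_days=10, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle, truth = g.simulate_cohort(params)
    return params, bundle, truth


@pytest.fixture(scope="session")
def observation_cohort():
    """Observation-level cohort at study scale for model recovery tests."""
    params = g.CohortParams(seed=7)
    obs, truth = g.simulate_observations(params, seed=7)
    obs = g.compute_composites(obs)
    obs["z_metabolic_state"] = g.z_standardise(obs["metabolic_state"])
    return params, obs, truth
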