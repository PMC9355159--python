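import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import lifescore as ls

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from lifescore.codebook import FactorSpec, FactorCodebook


@pytest.fixture(scope="session")
def codebook37():
    return ls.default_codebook()


@pytest.fixture(scope="session")
def small_cohort(codebook37):
    """4,000-participant default-codebook cohort (fixed seed)."""
    cfg = ls.SimulationConfig(n_participants=4000, seed=20220722)
    return ls.generate_cohort(cfg, codebook37)


@pytest.fixture(scope="session")
def analysis_small(small_cohort, codebook37):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        retained, _ = ls.apply_exclusions(small_cohort, ls.OutcomeDefinition(), codebook37)
        return ls.derive_factors(retained, codebook37)


@pytest.fixture
def binary_factor_codebook():
    """Single binary lifestyle factor with no planted effect."""
    spec = FactorSpec(
        name="factor_x",
        var_type="binary",
        marginal={"kind": "bernoulli", "p": 0.5},
        log_hazard=0.0,
        exposure={"kind": "equals", "value": 1},
    )
    return FactorCodebook([spec])


def make_survival_frame(rng, n, beta=0.0, censor_high=3.0):
    """Small tie-free survival dataset with one binary factor + age/sex."""
    x = rng.integers(0, 2, n)
    age = rng.normal(57, 8, n)
    male = rng.integers(0, 2, n)
    t = rng.exponential(1.0, n) * np.exp(-beta * x)
    cens = rng.uniform(0.2, censor_high, n)
    time = np.minimum(t, cens)
    event = (t <= cens).astype(int)
    return pd.DataFrame(
        {
            "factor_x": x,
            "age": age,
            "sex": np.where(male == 1, "male", "female"),
            "event_time": time,
            "ckd_event": event,
            "event_type": np.where(event == 1, "ckd", "censored"),
        }
    )


@pytest.fixture
def survival_frame_factory():
    return make_survival_frame
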