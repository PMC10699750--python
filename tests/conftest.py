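import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swimresp import (
    FishMorphometrics,
    TunnelGeometry,
    default_truth,
    simulate_trial,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tunnel() -> TunnelGeometry:
    return TunnelGeometry()


@pytest.fixture(scope="session")
def fish() -> FishMorphometrics:
    return FishMorphometrics(mass_kg=0.9, fork_length_cm=40.0, girth_cm=28.0,
                             ventricular_mass_g=0.8)


@pytest.fixture(scope="session")
def noise_free_truth_22():
    """Group-level 22 degC truth with noise off and Ucrit mid-step, so the
    exhaustion phase is long enough for closed-phase measurements."""
    base = default_truth(22.0)
    return dataclasses.replace(base, noise_sd_po2=0.0, noise_sd_flow=0.0,
                               ucrit_true=0.725)


@pytest.fixture(scope="session")
def noise_free_trial_22(noise_free_truth_22, fish, tunnel):
    return simulate_trial(noise_free_truth_22, fish, tunnel, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230)
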