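import itertools

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from asrtlearn.cohort import study1_config, simulate_cohort
from asrtlearn.design import make_pattern

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ALL_PERMUTATIONS = [p for p in itertools.permutations((1, 2, 3, 4))]


@pytest.fixture(scope="session")
def pattern():
    """The worked 4-R-2-R-3-R-1-R design."""
    return make_pattern((4, 2, 3, 1))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort reused across scoring/model tests."""
    cfg = study1_config(n_subjects=30, n_blocks=10, seed=42)
    profiles, trials, ef = simulate_cohort(cfg)
    return cfg, profiles, trials, ef


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
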