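import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sleeptrans.hypnogram import FOUR_STAGES, Hypnogram
from sleeptrans.simulate import Cohort, SimulationConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_hypnogram() -> Hypnogram:
    """The worked example night: W,W,L,L,L,D,R,R (8 epochs)."""
    return Hypnogram(stages=("W", "W", "L", "L", "L", "D", "R", "R"))


@pytest.fixture
def random_hypnogram_factory():
    def make(n_epochs: int, seed: int) -> Hypnogram:
        rng = np.random.default_rng(seed)
        stages = tuple(rng.choice(FOUR_STAGES, size=n_epochs))
        return Hypnogram(stages=stages)

    return make


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """A 6-subject confusion-channel cohort for pipeline-level tests."""
    cfg = SimulationConfig(n_subjects=6, n_epochs=300, seed=7)
    return simulate_cohort(cfg)
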