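import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")


@pytest.fixture
def geometry():
    from cogvergence import GeometryConfig
    return GeometryConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20240130)


@pytest.fixture
def small_event_log():
    """A deterministic 10-trial oddball schedule (2 targets)."""
    from cogvergence import generate_paradigm
    return generate_paradigm(n_trials=10, p_target=0.2, seed=7)


@pytest.fixture
def noiseless_params():
    """One-tracker, noise- and dropout-free simulation parameters."""
    from cogvergence import SimulationParams, TrackerSpec
    return SimulationParams(
        n_subjects=2,
        trackers={"ET": TrackerSpec(rate=30.0, noise_sd=0.0, dropout_prob=0.0)},
        subject_sd=0.0,
        seed=3,
    )
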