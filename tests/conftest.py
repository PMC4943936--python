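import numpy as np
import pytest

from cuedapproach.config import GeneratorConfig, LocomotionParams, condition_config


@pytest.fixture(scope="session")
def saline_config() -> GeneratorConfig:
    return condition_config("saline")


@pytest.fixture(scope="session")
def short_tracking_config() -> GeneratorConfig:
    """A 20-min session sized for tracking tests."""
    return condition_config("saline").replace(session_duration=1200.0)


@pytest.fixture(scope="session")
def tracked_session(short_tracking_config):
    """One generated session with a tracking trace, shared across tests."""
    from cuedapproach.simulate import simulate_session

    return simulate_session(short_tracking_config, seed=7, tracking=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def quiet_locomotion(**overrides) -> LocomotionParams:
    """Locomotion parameters with everything switched off unless overridden."""
    base = dict(
        bout_rate_responsive=0.0,
        bout_rate_nonresponsive=0.0,
        jitter_sd=0.0,
        gap_rate=0.0,
    )
    base.update(overrides)
    return LocomotionParams(**base)
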