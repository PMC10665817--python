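import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fiberflow as ff

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """One default synthetic session (fixed seed), shared across tests."""
    cfg = ff.SynthConfig(seed=1)
    rec, track, events, truth = ff.generate_session(cfg)
    return cfg, rec, track, events, truth


@pytest.fixture(scope="session")
def default_traces(default_session):
    _, rec, *_ = default_session
    return ff.deinterleave(rec)


@pytest.fixture(scope="session")
def default_zdff(default_session, default_traces):
    cfg, *_ = default_session
    signal = default_traces[cfg.led_channels[1]]
    reference = default_traces[cfg.led_channels[0]]
    return ff.compute_zdff(signal, reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
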