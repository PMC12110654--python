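import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import syncphase as sp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trace(values_z, fs=100.0, participant_id="p"):
    """Build an AccelTrace whose magnitude equals |values_z| (on az)."""
    v = np.asarray(values_z, dtype=float)
    t = np.arange(len(v)) / fs
    zeros = np.zeros_like(v)
    return sp.AccelTrace(participant_id, t, zeros, zeros, v, sample_rate_hz=fs)


@pytest.fixture
def toy_trace():
    """1000-sample 100 Hz trace with a smooth oscillation plus offset."""
    t = np.arange(1000) / 100.0
    return sp.AccelTrace(
        "toy", t, 0.1 * np.cos(2 * np.pi * 0.7 * t),
        np.zeros(1000), 1.0 + 0.2 * np.sin(2 * np.pi * 0.3 * t),
    )
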