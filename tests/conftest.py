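import logging

import numpy as np
import pytest

from gaitcfar import (
    DetectorParams,
    SyntheticGaitSpec,
    WindowParams,
    simulate_recording,
)

# the guard path (short unstable buffer -> threshold reuse) fires routinely
# at recording starts; keep its warning out of test logs
logging.getLogger("gaitcfar.cfar").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def default_windows():
    return WindowParams()


@pytest.fixture(scope="session")
def default_params():
    return DetectorParams()


@pytest.fixture(scope="session")
def short_walk():
    """8 s of synthetic walking at 4 km/h, 500 Hz (fast enough for unit tests)."""
    return simulate_recording(
        SyntheticGaitSpec(speed_kmh=4.0, duration_s=8.0, fs=500.0, seed=11)
    )


def random_force_stream(rng, n, tie_prob=0.2):
    """Random stream mixing drifts, noise and exact ties (for dF = 0 paths)."""
    steps = rng.choice([-1.0, 0.0, 1.0], size=n, p=[(1 - tie_prob) / 2, tie_prob, (1 - tie_prob) / 2])
    drift = np.repeat(rng.normal(0, 0.5, size=max(n // 50, 1)), 50)[:n]
    return np.cumsum(steps) + np.round(drift, 1)
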