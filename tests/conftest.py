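from datetime import datetime, timezone

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ciconia.accel import AccelBurst, BEHAVIORS
from ciconia.synthetic import SimConfig, simulate_burst

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_burst(surge, sway=None, heave=None, rate=1.0):
    """Small helper: burst from explicit sample vectors (defaults zero)."""
    surge = np.asarray(surge, dtype=float)
    sway = np.zeros_like(surge) if sway is None else np.asarray(sway, float)
    heave = np.zeros_like(surge) if heave is None else np.asarray(heave, float)
    return AccelBurst(
        individual="test",
        timestamp=datetime(2019, 5, 1, tzinfo=timezone.utc),
        surge=surge,
        sway=sway,
        heave=heave,
        rate=rate,
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def burst_corpus(sim_config):
    """1000 labeled synthetic bursts, 250 per behavior, at 10 Hz."""
    rng = np.random.default_rng(3)
    bursts, labels = [], []
    for behavior in BEHAVIORS:
        for _ in range(250):
            bursts.append(simulate_burst(behavior, sim_config, rng, rate_hz=10.0))
            labels.append(behavior)
    return bursts, labels
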