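import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import biosensorkit as bk

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def zero_noise_arac():
    """Noise-free AraC titration (1 replicate) for closed-form checks."""
    cfg = bk.preset_config(sensors=("AraC",), seed=0, noise=bk.ZERO_NOISE, replicates=1)
    return cfg, bk.simulate_plate(cfg)


@pytest.fixture(scope="session")
def default_noise_arac():
    cfg = bk.preset_config(sensors=("AraC",), seed=1)
    return cfg, bk.simulate_plate(cfg)


@pytest.fixture(scope="session")
def binary_state_samples():
    """All eight binary induction combinations of the three-channel strain."""
    from itertools import combinations

    inducers = ["glucarate", "erythromycin", "acrylate"]
    states = [frozenset(c) for r in range(4) for c in combinations(inducers, r)]
    return [bk.simulate_events(s, seed=100 + i) for i, s in enumerate(states)]


@pytest.fixture(scope="session")
def calibration_thresholds():
    off = bk.simulate_events(set(), seed=10)
    on = bk.simulate_events({"glucarate", "erythromycin", "acrylate"}, seed=11)
    return {ch: bk.derive_thresholds(off, on, ch) for ch in off.channels}


def make_well(times, od, values, channel="GFP", **condition_kwargs):
    cond = bk.Condition(
        sensor=condition_kwargs.pop("sensor", "S"),
        inducer=condition_kwargs.pop("inducer", "x"),
        **condition_kwargs,
    )
    return bk.WellTimeSeries(
        well=condition_kwargs.get("well", "W0"),
        condition=cond,
        times=np.asarray(times, dtype=float),
        od=np.asarray(od, dtype=float),
        fluorescence={channel: np.asarray(values, dtype=float)},
    )


@pytest.fixture
def well_factory():
    return make_well
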