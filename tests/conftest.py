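import numpy as np
import pytest

import ripvent as rv
from ripvent.config import RunConfig


def make_belts(thorax, abdomen, rate=25.0):
    return rv.BeltPair(rv.Signal(np.asarray(thorax, float), rate, label="Thorax"),
                       rv.Signal(np.asarray(abdomen, float), rate, label="Abdomen"))


def sinusoid_belts(freq=0.25, duration=60.0, rate=25.0, phase=0.0,
                   th_gain=1.0, ab_gain=1.0):
    t = np.arange(0.0, duration, 1.0 / rate)
    x = np.sin(2.0 * np.pi * freq * t + phase)
    return make_belts(th_gain * x, ab_gain * x, rate)


@pytest.fixture(scope="session")
def default_night():
    """One simulated 2-hour test night shared by the expensive tests."""
    cfg = rv.default_test_night(seed=7)
    belts, flow, truth = rv.simulate_recording(cfg)
    return cfg, belts, flow, truth


@pytest.fixture(scope="session")
def night_runs(default_night):
    """Corrected, benchmark and reference pipeline results on the night."""
    _, belts, flow, truth = default_night
    corrected = rv.process_belts(belts, RunConfig(method="corrected", seed=7))
    benchmark = rv.process_belts(belts, RunConfig(method="benchmark_2to1", seed=7))
    reference = rv.process_flow(flow, RunConfig(seed=7))
    return corrected, benchmark, reference
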