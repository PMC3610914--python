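import numpy as np
import pytest

from calcosc import DetectionParams, FluorescenceTrace, PhaseProtocol, load_presets


@pytest.fixture(scope="session")
def presets():
    """Preset table, loaded (and peak-calibrated) once per session."""
    return load_presets()


@pytest.fixture(scope="session")
def baseline(presets):
    return presets["baseline_d5"]


@pytest.fixture
def params():
    return DetectionParams()


@pytest.fixture
def protocol():
    return PhaseProtocol()


def random_walk_trace(seed: int, n: int = 300, neuron_id: str = "rw") -> FluorescenceTrace:
    """Positive random-walk-plus-spikes trace used by baseline oracle tests."""
    rng = np.random.default_rng(seed)
    v = 100.0 + np.cumsum(rng.normal(0, 1.0, n))
    spikes = rng.random(n) < 0.05
    v = v + spikes * rng.uniform(20, 80, n)
    v = np.maximum(v, 1.0)
    return FluorescenceTrace(neuron_id=neuron_id, values=v)
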