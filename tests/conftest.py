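import dataclasses

import numpy as np
import pytest

from abrwave.core import TimeGrid
from abrwave.simulator import NoiseSpec, default_templates, simulate_recording


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def quiet_noise() -> NoiseSpec:
    """No disturbance at all."""
    return NoiseSpec(
        baseline_sd=0.0,
        drift_amplitude=0.0,
        drift_period=1.0,
        late_artifact_prob=0.0,
        late_artifact_gain=0.0,
    )


@pytest.fixture
def deterministic_templates():
    """All waves present, no jitter, no amplitude variation."""
    return [
        dataclasses.replace(t, latency_sd=0.0, amplitude_sd=0.0, presence_prob=1.0)
        for t in default_templates()
    ]


@pytest.fixture
def clean_sweep(deterministic_templates, quiet_noise):
    """One noise-free, jitter-free normal sweep with its annotation."""
    return simulate_recording(
        deterministic_templates, quiet_noise, "normal", np.random.default_rng(0)
    )
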