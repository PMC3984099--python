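import numpy as np
import pytest

from spikecodec.synthdata import (
    GeometryConfig,
    default_electrode_positions,
    place_noise_neurons,
    place_target_neurons,
    synthesize_recording,
)
from spikecodec.workbench import default_fixed_bases, simulate_condition


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def short_recording():
    """20 s high-SNR single-site recording used by several modules."""
    return simulate_condition("high", duration=20.0, seed=7)


@pytest.fixture(scope="session")
def clean_recording():
    """One target neuron, no noise neurons, no thermal noise."""
    geom = GeometryConfig(electrode_positions=default_electrode_positions()[9:10])
    targets = place_target_neurons(seed=3)[:1]
    return synthesize_recording(geom, targets, [], duration=5.0, thermal_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def fixed_bases():
    """Prebuilt model-tuned and generic fixed bases (shared; expensive)."""
    return default_fixed_bases()
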