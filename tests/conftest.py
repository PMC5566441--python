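import numpy as np
import pytest

from selfiedpcr import SimulationParams, simulate_selfie_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20170821)


@pytest.fixture
def brain_params():
    """Whole-brain-like scenario: single-copy gene, ~608 gene copies per
    reaction, 1.95 transcripts per gene, clean amplitudes."""
    return SimulationParams(seed=42, rain_fraction=0.0)


@pytest.fixture
def brain_pair(brain_params):
    return simulate_selfie_pair(brain_params)
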