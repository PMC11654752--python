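import numpy as np
import pytest

from dynphantom.calibration import characterize_channel
from dynphantom.phantom_model import default_phantom
from dynphantom.waveforms import max_normalize, resample, synth_ppg


@pytest.fixture(scope="session")
def phantom():
    """Noiseless four-channel fixture."""
    return default_phantom()


@pytest.fixture(scope="session")
def luts(phantom):
    """Noiseless lookup tables for all four channels."""
    return {nm: characterize_channel(phantom, nm) for nm in phantom.channels}


@pytest.fixture(scope="session")
def norm_ppg_50hz():
    """Max-normalized 75 bpm, 6 s PPG at the 50 Hz measurement rate."""
    return resample(max_normalize(synth_ppg(75, 6.0, 1000.0, seed=3)), 50.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
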