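import numpy as np
import pytest

from neuromove import synthetic as syn


@pytest.fixture(scope="session")
def reach_schedule():
    return syn.generate_block_schedule("reach", "nondominant", "SAU", 3)


@pytest.fixture(scope="session")
def steer_schedule():
    return syn.generate_block_schedule("steer", "dominant", None, 3)


@pytest.fixture(scope="session")
def small_montage():
    """Two-channel EEG montage (one per hemisphere) for fast spectral tests."""
    return {"C3": "left", "C4": "right"}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
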