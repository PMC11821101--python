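import numpy as np
import pytest

from cdkd import FrameSequence, PhantomConfig, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(20250920)


@pytest.fixture()
def random_sequence(rng):
    """Six random 16x16 frames with 8-bit dynamic range."""
    frames = rng.integers(0, 256, size=(6, 16, 16)).astype(float)
    return FrameSequence(frames, max_value=255.0)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 30-frame phantom with period 10 (3 full cycles)."""
    return generate_phantom(PhantomConfig(n_frames=30, period=10.0, noise_sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def default_phantom():
    """Phantom at generator defaults (60 frames, period 20, noise-free)."""
    return generate_phantom(PhantomConfig())
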