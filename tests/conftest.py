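import numpy as np
import pytest

from vtreg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """Default 64x64 phantom: 40 frames, 3 closures, moving tongue and jaw."""
    return generate_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def still_phantom():
    """Zero-motion, noise-free phantom (all frames identical)."""
    return generate_phantom(PhantomSpec(
        n_frames=6, n_closures=0, palate_amplitude=0.0, tongue_amplitude=0.0,
        noise_sd=0.0, seed=3,
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
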