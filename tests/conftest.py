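import numpy as np
import pytest

from sparsedev.synthimg import GaborSpec, generate_gabor_rf


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def smooth_gabor():
    """A noiseless, band-limited Gabor for transform-accuracy checks."""
    spec = GaborSpec(
        center=(7.5, 7.5),
        orientation=0.6,
        frequency=0.08,
        phase=0.3,
        sigma_along=3.5,
        sigma_across=2.5,
    )
    return generate_gabor_rf(spec, 16)


@pytest.fixture(scope="session")
def gabor_stack():
    """Small stack of diverse noiseless Gabors (16 x 16)."""
    from sparsedev.synthimg import generate_gabor_set

    return generate_gabor_set(8, 16, seed=7)
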