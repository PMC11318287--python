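"""Shared fixtures: small deterministic images and phantom datasets."""

import numpy as np
import pytest

from nriqa import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_phantom():
    """A 64x64 piecewise-smooth phantom with mild texture."""
    return phantom.generate_phantom(64, 3, 0.3, seed=1)


@pytest.fixture
def noisy_pair(clean_phantom):
    """(clean, noisy) pair at the lowest study noise level."""
    noisy = phantom.add_noise(clean_phantom, 0.2, "gaussian", seed=2)
    return clean_phantom, noisy


@pytest.fixture
def random_image(rng):
    return rng.random((16, 16))
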