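import numpy as np
import pytest

from gfptract.simulate import ImagingParams, simulate_tract_image


@pytest.fixture(scope="session")
def noisy_scene():
    """One default (noise-on) simulated sample."""
    return simulate_tract_image(ImagingParams(seed=42))


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free simulated sample (idealized optics: float intensities)."""
    params = ImagingParams(seed=42, poisson_gain=0.0, read_noise_sd=0.0)
    return simulate_tract_image(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
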