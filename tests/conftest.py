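import numpy as np
import pytest

from radrobust.phantom import ObserverModel, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One deterministic mid-size phantom shared across tests."""
    spec = PhantomSpec(seed=42)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free, unspiculated, sharp-edged sphere (easy segmentation case)."""
    spec = PhantomSpec(noise_sd=0.0, spiculation_count=0, edge_blur_fwhm=0.0, seed=7)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
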