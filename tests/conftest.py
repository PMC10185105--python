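import numpy as np
import pytest

from legcomp import (
    PhantomSpec,
    SegmentationConfig,
    generate_phantom,
    segment_volume,
)


@pytest.fixture(scope="session")
def default_config():
    return SegmentationConfig()


@pytest.fixture(scope="session")
def small_phantom():
    """12-slice phantom at default bias field and noise."""
    spec = PhantomSpec(n_slices=12, seed=42)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    """12-slice phantom with the bias field and noise switched off."""
    spec = PhantomSpec(n_slices=12, seed=7, noise_sigma=0.0, bias_field_amplitude=0.0)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def segmented_small(small_phantom, default_config):
    _, volume, truth = small_phantom
    return segment_volume(volume, default_config), volume, truth


@pytest.fixture(scope="session")
def segmented_noiseless(noiseless_phantom, default_config):
    _, volume, truth = noiseless_phantom
    return segment_volume(volume, default_config), volume, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
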