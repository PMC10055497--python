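import numpy as np
import pytest

from sbrnet import DisparityModel, OpticsConfig, synth_psf_stack


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def desk_config():
    """Reduced working grid used throughout the CPU-scale tests."""
    return OpticsConfig().desk(grid_px=224, view_px=64, lenslet_pitch_px=72.0,
                               fov_diameter_um=200.0)


@pytest.fixture(scope="session")
def desk_disparity(desk_config):
    return DisparityModel.from_config(desk_config)


@pytest.fixture(scope="session")
def desk_psf(desk_config, desk_disparity):
    return synth_psf_stack(desk_config, desk_disparity)


@pytest.fixture(scope="session")
def tiny_config():
    """Very small grid for convolution/refocus oracles."""
    return OpticsConfig().desk(grid_px=96, view_px=32, lenslet_pitch_px=30.0,
                               fov_diameter_um=100.0)
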