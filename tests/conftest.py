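import numpy as np
import pytest

from zygoquant.geometry import EllipsoidDims
from zygoquant.synthetic import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene():
    """A coarse, fast-to-render scene for image-based tests."""
    return SceneConfig(
        embryo=EllipsoidDims(8.0, 4.0, 4.0),
        pixel_size_um=0.2,
        z_step_um=0.5,
        psf_sigma_um=0.3,
        n_puncta=5,
        n_masses=0,
        cloud_sigma_um=2.0,
        noise_sd=0.0,
        background_level=0.0,
        seed=7,
    )
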