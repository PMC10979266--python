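import numpy as np
import pytest
from scipy import ndimage as ndi

from trabeculex import GrayImage, TrabecularParams, generate_trabecular_roi


def random_blob_mask(rng: np.random.Generator, shape=(60, 60), smooth=3.0,
                     fill=0.45) -> np.ndarray:
    """Random connected-blob mask from a thresholded smoothed noise field."""
    field = ndi.gaussian_filter(rng.standard_normal(shape), smooth)
    return field > np.quantile(field, 1.0 - fill)


@pytest.fixture
def rng():
    return np.random.default_rng(20240322)


@pytest.fixture
def noiseless_params():
    return TrabecularParams(bone_fraction=0.5, correlation_length_mm=0.5,
                            gradient_amplitude=0.0, noise_sd=0.0, seed=11)


@pytest.fixture
def noiseless_roi(noiseless_params):
    return generate_trabecular_roi(noiseless_params)


@pytest.fixture
def gradient_image():
    """100x100 image linear in the column index, 0.1 mm pixels."""
    col = np.linspace(40, 200, 100)
    return GrayImage(np.tile(col, (100, 1)), 0.1)
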