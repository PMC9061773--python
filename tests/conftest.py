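import numpy as np
import pytest

from stressfiber.io_formats import Image2D
from stressfiber.decomposition import DictionaryConfig
from stressfiber.segmentation import ExtractionConfig, extract_filaments
from stressfiber.synthetic import SyntheticSpec, generate_fiber_image, _draw_soft_line


@pytest.fixture(scope="session")
def fast_config() -> ExtractionConfig:
    """Reduced-size pipeline settings for small test images."""
    return ExtractionConfig(
        min_length_px=12,
        n_iterations=40,
        line_widths=(1, 3),
        dictionary=DictionaryConfig(n_wavelet_levels=3),
    )


@pytest.fixture(scope="session")
def parallel_fixture():
    """256x256 image of 20 parallel fibers at 30 deg, no noise, with truth."""
    spec = SyntheticSpec(
        image_shape=(256, 256), n_fibers=20, kappa=1e6, mean_angle_deg=30.0,
        length_range_px=(60, 100), width_px=3, noise_sigma=0.0, n_blobs=0,
        seed=1,
    )
    return generate_fiber_image(spec)


@pytest.fixture(scope="session")
def parallel_extraction(parallel_fixture):
    img, _truth = parallel_fixture
    return extract_filaments(img)


@pytest.fixture()
def line_image():
    """96x96 image with one horizontal 3-px line on row 48."""
    canvas = np.zeros((96, 96))
    _draw_soft_line(canvas, 15, 48, 80, 48, 3, 1.0)
    return Image2D(canvas)
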