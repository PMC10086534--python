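import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_raster(arr, **kw):
    from adiposcope.imaging_core import RasterImage

    return RasterImage(np.asarray(arr, dtype=float), **kw)


def make_rgb(r, g, b):
    from adiposcope.imaging_core import RGBImage

    return RGBImage(
        np.asarray(r, dtype=float),
        np.asarray(g, dtype=float),
        np.asarray(b, dtype=float),
    )


def rgb_from_pixel(rgb_triplet, shape=(1, 1)):
    """Uniform RGBImage holding one color."""
    r, g, b = rgb_triplet
    return make_rgb(
        np.full(shape, float(r)), np.full(shape, float(g)), np.full(shape, float(b))
    )
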