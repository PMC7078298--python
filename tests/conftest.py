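import numpy as np
import pytest

from gliaquant.io import FieldImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def make_field():
    """Factory for a calibrated FieldImage from a raw 2-D array."""

    def _make(pixels, pixel_size_um=1.0):
        return FieldImage(
            pixels=np.asarray(pixels, dtype=np.float64), pixel_size_um=pixel_size_um
        )

    return _make


@pytest.fixture
def disc_field(make_field):
    """Field with bright discs drawn at requested (y, x) um positions."""

    def _make(centers_um, radius_um=4.0, pixel_size_um=1.0, shape=(200, 200), amplitude=200.0):
        img = np.zeros(shape)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        for cy, cx in centers_um:
            r2 = (yy * pixel_size_um - cy) ** 2 + (xx * pixel_size_um - cx) ** 2
            img[r2 <= radius_um**2] = amplitude
        return make_field(img, pixel_size_um)

    return _make
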