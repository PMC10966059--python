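import numpy as np
import pytest

from ccfd.geometry import BinaryMask, EnFaceImage, ImageGeometry


@pytest.fixture
def geom_default() -> ImageGeometry:
    """The standard 6 x 6 mm / 1024 px export geometry."""
    return ImageGeometry(6.0, 1024)


@pytest.fixture
def geom_small() -> ImageGeometry:
    """A 6 mm field at coarse resolution for fast tests."""
    return ImageGeometry(6.0, 128)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)


def make_image(pixels, geometry=None, modality="flow"):
    pixels = np.asarray(pixels, dtype=float)
    geometry = geometry or ImageGeometry(6.0, pixels.shape[0])
    return EnFaceImage(pixels, geometry=geometry, modality=modality)


def make_mask(pixels, geometry=None, label=""):
    pixels = np.asarray(pixels, dtype=bool)
    geometry = geometry or ImageGeometry(6.0, pixels.shape[0])
    return BinaryMask(pixels, geometry=geometry, label=label)
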