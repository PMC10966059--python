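"""Structural signal compensation of the en-face flow image.

Flow signal under pigment-epithelium pathology is attenuated by the overlying
tissue; the compensation stage corrects for this by (1) inverting the en-face
structural image on the normalized [0, 1] scale, (2) smoothing the inverted
image with a small Gaussian kernel to suppress speckle, and (3) multiplying
the flow image by the result.  Where the structural signal is weak (dark), the
inverted image is bright and the flow signal is boosted; where the structural
signal saturates, flow is suppressed.

The smoothing kernel is a hard-truncated, renormalized 3 x 3 discrete
Gaussian by default (sigma 0.85 px), applied with reflective boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import GeometryError
from .geometry import EnFaceImage

__all__ = [
    "CompensationParams",
    "invert_image",
    "gaussian_smooth",
    "compensate_flow",
]


@dataclass(frozen=True)
class CompensationParams:
    """Parameters of the compensation stage.

    kernel_size_px : odd kernel side length (default 3)
    kernel_sigma_px : Gaussian sigma in pixels (default 0.85)
    rescale : divide the compensated image by its maximum so it spans [0, 1]
    """

    kernel_size_px: int = 3
    kernel_sigma_px: float = 0.85
    rescale: bool = True

    def __post_init__(self) -> None:
        if self.kernel_size_px < 1 or self.kernel_size_px % 2 == 0:
            raise ValueError(f"kernel_size_px must be odd and >= 1, got {self.kernel_size_px}")
        if not (self.kernel_sigma_px > 0):
            raise ValueError(f"kernel_sigma_px must be > 0, got {self.kernel_sigma_px}")

    def kernel(self) -> np.ndarray:
        """The normalized, truncated Gaussian kernel."""
        half = self.kernel_size_px // 2
        ax = np.arange(-half, half + 1, dtype=np.float64)
        g = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2.0 * self.kernel_sigma_px**2))
        return g / g.sum()


def invert_image(img: EnFaceImage) -> EnFaceImage:
    """Pixelwise inverse transform ``1 - I`` on normalized intensities.

    An involution: applying it twice returns the original image.
    """
    img.require_normalized()
    return img.with_pixels(1.0 - img.pixels)


def gaussian_smooth(img: EnFaceImage, params: CompensationParams | None = None) -> EnFaceImage:
    """Convolve with the normalized truncated Gaussian kernel (reflective edges)."""
    params = params or CompensationParams()
    out = ndimage.correlate(img.pixels, params.kernel(), mode="reflect")
    return img.with_pixels(np.clip(out, 0.0, None))


def compensate_flow(
    flow: EnFaceImage,
    structure: EnFaceImage,
    params: CompensationParams | None = None,
) -> EnFaceImage:
    """Compensated flow image: ``flow * smooth(invert(structure))``.

    Both inputs must be normalized to [0, 1] and share one geometry.  With
    ``params.rescale`` (the default) the product is divided by its maximum so
    the result again spans [0, 1]; an identically zero product passes through
    unchanged.  Before rescaling, the operation is linear in the flow image
    and monotone in the darkness of the structural image.
    """
    params = params or CompensationParams()
    if flow.geometry != structure.geometry:
        raise GeometryError("flow and structure images must share one geometry")
    flow.require_normalized()
    gain = gaussian_smooth(invert_image(structure), params).pixels
    out = flow.pixels * gain
    if params.rescale:
        peak = out.max(initial=0.0)
        if peak > 0:
            out = out / peak
    return EnFaceImage(out, geometry=flow.geometry, modality="flow", slab=flow.slab)
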