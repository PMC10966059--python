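"""Raster geometry and the core image containers.

Everything downstream operates on square en-face rasters tied to a physical
field of view.  The default geometry is the 6 x 6 mm macular field exported at
1024 x 1024 pixels, giving a pixel pitch of 6000/1024 = 5.859 um.  Physical
distances are measured between pixel centres, with the origin at the top-left
pixel centre (row-major).

Three containers are defined here:

``EnFaceImage``
    A 2-D grid of non-negative scalar intensities with a modality tag
    (``"flow"`` for the OCTA decorrelation signal, ``"structure"`` for the
    OCT reflectance projection) and an optional axial slab label.
    Intensities are floating point regardless of on-disk bit depth.

``BinaryMask``
    A 2-D boolean grid sharing an image geometry; used for lesions, flow
    deficits, rings and whole-field regions.

``SlabSpec``
    An axial sub-volume below the RPE-fit centreline, e.g. 11-21 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import GeometryError, NormalizationError

__all__ = [
    "ImageGeometry",
    "SlabSpec",
    "EnFaceImage",
    "BinaryMask",
    "CANONICAL_SLABS",
    "pixel_pitch",
    "area_mm2",
]


@dataclass(frozen=True)
class ImageGeometry:
    """Physical geometry of a square en-face raster.

    Parameters
    ----------
    field_width_mm
        Physical width of the square field of view, in millimetres.
    grid_size_px
        Number of pixels per side.
    """

    field_width_mm: float = 6.0
    grid_size_px: int = 1024

    def __post_init__(self) -> None:
        if not (self.field_width_mm > 0):
            raise GeometryError(f"field_width_mm must be > 0, got {self.field_width_mm}")
        if int(self.grid_size_px) != self.grid_size_px or self.grid_size_px < 64:
            raise GeometryError(f"grid_size_px must be an integer >= 64, got {self.grid_size_px}")

    @property
    def pixel_pitch_um(self) -> float:
        """Centre-to-centre pixel spacing in micrometres."""
        return self.field_width_mm * 1000.0 / self.grid_size_px

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_pitch_um / 1000.0) ** 2

    @property
    def field_area_mm2(self) -> float:
        return self.field_width_mm**2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.grid_size_px, self.grid_size_px)


def pixel_pitch(geometry: ImageGeometry) -> float:
    """Pixel pitch of *geometry* in micrometres.

    On the default 6 mm / 1024 px grid this is 5.859375 um, so the 3-pixel
    local-threshold radius used downstream corresponds to ~17.6 um.
    """
    return geometry.pixel_pitch_um


@dataclass(frozen=True)
class SlabSpec:
    """An axial slab below the RPE-fit centreline (offsets in micrometres)."""

    inner_offset_um: float
    outer_offset_um: float
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.outer_offset_um > self.inner_offset_um):
            raise GeometryError(
                f"outer offset ({self.outer_offset_um}) must exceed inner ({self.inner_offset_um})"
            )
        if not self.name:
            object.__setattr__(
                self, "name", f"{self.inner_offset_um:g}-{self.outer_offset_um:g}um"
            )

    @property
    def thickness_um(self) -> float:
        return self.outer_offset_um - self.inner_offset_um


#: The three 10-um-thick axial positions analysed throughout: 11-21, 21-31 and
#: 31-41 um below the RPE-fit centreline.  The shallowest sits at the presumed
#: anatomical position of the choriocapillaris; the deeper two are "inner
#: choroid" slabs.
CANONICAL_SLABS: tuple[SlabSpec, ...] = (
    SlabSpec(11.0, 21.0),
    SlabSpec(21.0, 31.0),
    SlabSpec(31.0, 41.0),
)


@dataclass
class EnFaceImage:
    """A 2-D scalar en-face projection with physical geometry."""

    pixels: np.ndarray
    geometry: ImageGeometry = field(default_factory=ImageGeometry)
    modality: str = "flow"
    slab: SlabSpec | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != self.geometry.shape:
            raise GeometryError(
                f"pixel grid {self.pixels.shape} does not match geometry {self.geometry.shape}"
            )
        if self.modality not in ("flow", "structure"):
            raise ValueError(f"modality must be 'flow' or 'structure', got {self.modality!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise NormalizationError("image intensities must all be finite")
        if self.pixels.size and self.pixels.min() < 0:
            raise NormalizationError("image intensities must be non-negative")

    @property
    def is_normalized(self) -> bool:
        """True if intensities lie in [0, 1]."""
        return bool(self.pixels.max(initial=0.0) <= 1.0 + 1e-12)

    def require_normalized(self) -> None:
        if not self.is_normalized:
            raise NormalizationError(
                f"operation requires intensities in [0, 1]; max is {self.pixels.max():g}"
            )

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceImage":
        return replace(self, pixels=pixels)


@dataclass
class BinaryMask:
    """A 2-D boolean grid sharing an :class:`ImageGeometry`."""

    pixels: np.ndarray
    geometry: ImageGeometry = field(default_factory=ImageGeometry)
    label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.shape != self.geometry.shape:
            raise GeometryError(
                f"mask grid {self.pixels.shape} does not match geometry {self.geometry.shape}"
            )

    @property
    def count(self) -> int:
        """Number of true pixels."""
        return int(self.pixels.sum())

    @property
    def area_mm2(self) -> float:
        return self.count * self.geometry.pixel_area_mm2

    @property
    def is_empty(self) -> bool:
        return not self.pixels.any()

    def equivalent_radius_mm(self) -> float:
        """Radius of the circle with the same area."""
        return math.sqrt(self.area_mm2 / math.pi)


def area_mm2(mask: BinaryMask) -> float:
    """Physical area of the true pixels of *mask*, in mm^2.

    Additive over disjoint masks and monotone under union; zero for an empty
    mask.
    """
    return mask.area_mm2


def require_same_geometry(*items) -> ImageGeometry:
    """Check that all images/masks share one geometry; return it."""
    geoms = {item.geometry for item in items}
    if len(geoms) != 1:
        raise GeometryError(f"expected a single shared geometry, got {len(geoms)}: {geoms}")
    return next(iter(geoms))
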