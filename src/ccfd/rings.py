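"""Concentric perilesional rings by Euclidean distance from the lesion.

Successive 100-um-wide rings are built around the atrophic lesion border from
the exact Euclidean distance transform of the lesion complement (distance to
the nearest lesion pixel, in micrometres).  Ring k (1-based, width w) contains
the non-lesion pixels with distance in the half-open band ((k-1)w, kw]; a
pixel exactly at distance kw belongs to ring k.  Rings are pairwise disjoint,
never overlap the lesion, and follow the lesion border for arbitrary
(including multifocal) lesion shapes — the distance is taken to the nearest
focus.

Rings running past the field of view are clipped at the boundary but
retained: FD% is a ratio and is robust to partial rings.  The fraction of
each ring lost to clipping is computed against an enlarged virtual field and
reported so heavily clipped rings can be excluded by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .binarize import DeficitMap, fd_percent
from .exceptions import EmptyRegionError
from .geometry import BinaryMask

__all__ = ["RingSet", "distance_from_lesion", "build_rings", "ring_fd_profile"]


def distance_from_lesion(lesion: BinaryMask) -> np.ndarray:
    """Euclidean distance (um) from each pixel centre to the nearest lesion pixel.

    Zero inside the lesion.  Raises for an empty lesion mask.
    """
    if lesion.is_empty:
        raise EmptyRegionError("distance field is undefined for an empty lesion")
    d_px = ndimage.distance_transform_edt(~lesion.pixels)
    return d_px * lesion.geometry.pixel_pitch_um


@dataclass
class RingSet:
    """Ordered disjoint rings at increasing distance bands from a lesion."""

    rings: list[BinaryMask]
    ring_width_um: float
    lesion: BinaryMask
    clipped: list[float]  #: per-ring fraction lost to the field boundary
    touches_border: bool = False
    label_image: np.ndarray = field(repr=False, default=None)  #: ring index per pixel, 0 elsewhere

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    def areas_mm2(self) -> list[float]:
        return [r.area_mm2 for r in self.rings]


def build_rings(
    lesion: BinaryMask, ring_width_um: float = 100.0, n_rings: int = 12
) -> RingSet:
    """Build *n_rings* successive rings of width *ring_width_um* around *lesion*.

    The grid of rings depends only on the lesion mask and the two parameters,
    so it is distinctive to each case and identical across slabs of one eye.
    A lesion touching the field border triggers a warning but rings are still
    built.
    """
    if n_rings < 1:
        raise ValueError(f"n_rings must be >= 1, got {n_rings}")
    if not (ring_width_um > 0):
        raise ValueError(f"ring_width_um must be > 0, got {ring_width_um}")
    geom = lesion.geometry
    pitch = geom.pixel_pitch_um
    d = distance_from_lesion(lesion)

    border = np.zeros(geom.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touches = bool((lesion.pixels & border).any())
    if touches:
        warnings.warn("lesion touches the field border; rings may be heavily clipped")

    w = float(ring_width_um)
    # ring index per pixel: ceil(d / w) over (0, n*w], 0 for lesion and beyond
    with np.errstate(invalid="ignore"):
        idx = np.ceil(d / w).astype(np.int32)
    idx[lesion.pixels] = 0
    idx[d > n_rings * w] = 0
    idx[d <= 0] = 0

    # unclipped reference areas from a padded virtual field
    pad = int(np.ceil(n_rings * w / pitch)) + 2
    padded = np.pad(lesion.pixels, pad)
    d_pad = ndimage.distance_transform_edt(~padded) * pitch
    idx_pad = np.ceil(d_pad / w).astype(np.int32)
    idx_pad[padded] = 0
    idx_pad[d_pad > n_rings * w] = 0
    idx_pad[d_pad <= 0] = 0

    counts = np.bincount(idx.ravel(), minlength=n_rings + 1)
    counts_pad = np.bincount(idx_pad.ravel(), minlength=n_rings + 1)

    rings, clipped = [], []
    for k in range(1, n_rings + 1):
        rings.append(BinaryMask(idx == k, geometry=geom, label=f"ring-{k}"))
        full = counts_pad[k]
        clipped.append(float(1.0 - counts[k] / full) if full > 0 else 0.0)

    return RingSet(
        rings=rings,
        ring_width_um=w,
        lesion=lesion,
        clipped=clipped,
        touches_border=touches,
        label_image=idx,
    )


def ring_fd_profile(dm: DeficitMap, rings: RingSet) -> list[float | None]:
    """FD% for each ring in order; rings with zero pixels report ``None``.

    A ring that exists but contains no deficit pixels reports 0.0 — missing
    and zero are distinct outcomes.
    """
    out: list[float | None] = []
    for ring in rings.rings:
        if ring.is_empty:
            out.append(None)
        else:
            out.append(fd_percent(dm, ring))
    return out
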