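"""Reading and writing en-face images and masks.

Images go to grayscale TIFF (16-bit) or PNG, masks to 0/255 PNG; geometry and
slab metadata travel in a JSON sidecar next to each raster (``<stem>.json``).
Integer rasters are rescaled to [0, 1] on read so the analysis is bit-depth
independent (8- and 16-bit files are both accepted).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .geometry import BinaryMask, EnFaceImage, ImageGeometry, SlabSpec

__all__ = ["write_enface", "read_enface", "write_mask", "read_mask"]

_INT_SCALE = {np.uint8: 255.0, np.uint16: 65535.0}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def _geometry_meta(geometry: ImageGeometry) -> dict:
    return {
        "field_width_mm": geometry.field_width_mm,
        "grid_size_px": geometry.grid_size_px,
    }


def _geometry_from_meta(meta: dict) -> ImageGeometry:
    return ImageGeometry(
        field_width_mm=meta["field_width_mm"], grid_size_px=meta["grid_size_px"]
    )


def write_enface(img: EnFaceImage, path: str | Path) -> Path:
    """Write *img* as 16-bit grayscale TIFF/PNG plus a JSON sidecar.

    Intensities are clipped to [0, 1] and scaled to the full 16-bit range.
    """
    path = Path(path)
    data = np.clip(img.pixels, 0.0, 1.0)
    raw = np.round(data * 65535.0).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raw)
    else:
        iio.imwrite(path, raw)
    meta = {
        "kind": "enface",
        "modality": img.modality,
        "geometry": _geometry_meta(img.geometry),
    }
    if img.slab is not None:
        meta["slab"] = {
            "inner_offset_um": img.slab.inner_offset_um,
            "outer_offset_um": img.slab.outer_offset_um,
            "name": img.slab.name,
        }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_enface(path: str | Path) -> EnFaceImage:
    """Read a TIFF/PNG en-face image, rescaling integer data to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
    else:
        raw = iio.imread(path)
    raw = np.asarray(raw)
    if raw.ndim == 3:  # collapse any accidental colour axis
        raw = raw[..., 0]
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        data = raw.astype(np.float64) / scale
    else:
        data = raw.astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())
    slab = None
    if "slab" in meta:
        s = meta["slab"]
        slab = SlabSpec(s["inner_offset_um"], s["outer_offset_um"], s.get("name", ""))
    return EnFaceImage(
        pixels=data,
        geometry=_geometry_from_meta(meta["geometry"]),
        modality=meta.get("modality", "flow"),
        slab=slab,
    )


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write *mask* as a 0/255 PNG plus a JSON sidecar."""
    path = Path(path)
    iio.imwrite(path, np.where(mask.pixels, 255, 0).astype(np.uint8))
    meta = {
        "kind": "mask",
        "label": mask.label,
        "geometry": _geometry_meta(mask.geometry),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_mask(path: str | Path) -> BinaryMask:
    path = Path(path)
    raw = np.asarray(iio.imread(path))
    if raw.ndim == 3:
        raw = raw[..., 0]
    meta = json.loads(_sidecar(path).read_text())
    return BinaryMask(
        pixels=raw > 127,
        geometry=_geometry_from_meta(meta["geometry"]),
        label=meta.get("label", ""),
    )


# ---------------------------------------------------------------------------
# cohort directories


def write_eye(eye, directory: str | Path) -> Path:
    """Write one EyeCase: slab images as TIFF, masks as PNG, metadata as JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    slabs_meta = []
    for slab, (flow, structure) in eye.slabs.items():
        write_enface(flow, directory / f"flow_{slab.name}.tif")
        write_enface(structure, directory / f"structure_{slab.name}.tif")
        slabs_meta.append(
            {
                "inner_offset_um": slab.inner_offset_um,
                "outer_offset_um": slab.outer_offset_um,
                "name": slab.name,
            }
        )
    for g, (b, f) in enumerate(zip(eye.lesion_baseline, eye.lesion_followup), start=1):
        write_mask(b, directory / f"lesion_baseline_g{g}.png")
        write_mask(f, directory / f"lesion_followup_g{g}.png")
    meta = {
        "patient_id": eye.patient_id,
        "eye_id": eye.eye_id,
        "fu_years": eye.fu_years,
        "n_graders": len(eye.lesion_baseline),
        "slabs": slabs_meta,
        "truth": eye.truth,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))
    return directory


def read_eye(directory: str | Path):
    """Read an EyeCase written by :func:`write_eye`."""
    from .geometry import SlabSpec
    from .synthetic import EyeCase

    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    slabs = {}
    for s in meta["slabs"]:
        slab = SlabSpec(s["inner_offset_um"], s["outer_offset_um"], s.get("name", ""))
        flow = read_enface(directory / f"flow_{slab.name}.tif")
        structure = read_enface(directory / f"structure_{slab.name}.tif")
        slabs[slab] = (flow, structure)
    baselines, followups = [], []
    for g in range(1, meta["n_graders"] + 1):
        baselines.append(read_mask(directory / f"lesion_baseline_g{g}.png"))
        followups.append(read_mask(directory / f"lesion_followup_g{g}.png"))
    return EyeCase(
        patient_id=meta["patient_id"],
        eye_id=meta["eye_id"],
        slabs=slabs,
        lesion_baseline=baselines,
        lesion_followup=followups,
        fu_years=meta["fu_years"],
        truth=meta.get("truth", {}),
    )


def write_cohort(eyes, directory: str | Path) -> Path:
    """Write an iterable of EyeCases plus a manifest CSV; returns the directory.

    Accepts a lazy iterator so a large cohort never needs to sit in memory.
    """
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for eye in eyes:
        eye_dir = write_eye(eye, directory / eye.eye_id)
        rows.append(
            {
                "eye_id": eye.eye_id,
                "patient_id": eye.patient_id,
                "path": eye_dir.name,
                "fu_years": eye.fu_years,
                "n_graders": len(eye.lesion_baseline),
            }
        )
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    return directory


def iter_cohort_dir(directory: str | Path):
    """Yield EyeCases listed in a cohort directory's manifest."""
    import pandas as pd

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    for _, row in manifest.iterrows():
        yield read_eye(directory / row["path"])


# ---------------------------------------------------------------------------
# audit exports


def write_compensation_stages(flow, structure, directory: str | Path, params=None) -> Path:
    """Write the intermediate compensation images (inverted, smoothed,
    compensated) as TIFFs for audit, alongside the inputs."""
    from .compensation import compensate_flow, gaussian_smooth, invert_image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    inverted = invert_image(structure)
    smoothed = gaussian_smooth(inverted, params)
    compensated = compensate_flow(flow, structure, params)
    write_enface(flow, directory / "flow.tif")
    write_enface(structure, directory / "structure.tif")
    write_enface(inverted, directory / "structure_inverted.tif")
    write_enface(smoothed, directory / "structure_inverted_smoothed.tif")
    write_enface(compensated, directory / "flow_compensated.tif")
    return directory


def component_table(dm):
    """Per-deficit table: id, pixel count, area, equivalent diameter, centroid."""
    import pandas as pd
    from scipy import ndimage

    ids = [c.component_id for c in dm.components]
    if ids:
        centroids = ndimage.center_of_mass(dm.mask.pixels, dm.labels, ids)
    else:
        centroids = []
    return pd.DataFrame(
        [
            {
                "component_id": c.component_id,
                "pixel_count": c.pixel_count,
                "area_um2": c.area_um2,
                "equivalent_diameter_um": c.equivalent_diameter_um,
                "centroid_row": cy,
                "centroid_col": cx,
            }
            for c, (cy, cx) in zip(dm.components, centroids)
        ]
    )


def write_deficit_map(dm, png_path: str | Path, csv_path: str | Path | None = None):
    """Write the deficit mask as PNG and (optionally) its component CSV."""
    write_mask(dm.mask, png_path)
    if csv_path is not None:
        component_table(dm).to_csv(csv_path, index=False)
    return Path(png_path)


def write_ring_set(rings, png_path: str | Path, csv_path: str | Path | None = None):
    """Write a ring grid as one labelled PNG (ring index as pixel value, 0
    elsewhere) plus a CSV of ring areas and clipped fractions."""
    import pandas as pd

    png_path = Path(png_path)
    iio.imwrite(png_path, rings.label_image.astype(np.uint8))
    _sidecar(png_path).write_text(
        json.dumps(
            {
                "kind": "ring-labels",
                "ring_width_um": rings.ring_width_um,
                "n_rings": rings.n_rings,
                "geometry": _geometry_meta(rings.lesion.geometry),
            },
            indent=1,
        )
    )
    if csv_path is not None:
        pd.DataFrame(
            {
                "ring": range(1, rings.n_rings + 1),
                "area_mm2": rings.areas_mm2(),
                "clipped_fraction": rings.clipped,
            }
        ).to_csv(csv_path, index=False)
    return png_path
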