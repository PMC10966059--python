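"""Synthetic OCTA cohorts with the statistical structure the analysis assumes.

Each synthetic eye consists of per-slab flow/structure en-face image pairs, a
baseline and follow-up lesion mask per grader, and a follow-up interval.  The
generator plants the features the pipeline is designed to detect:

* a capillary flow texture — a stationary Gaussian random field with a
  tunable correlation length — softly thresholded so that the expected
  flow-deficit fraction far from the lesion matches ``baseline_fd_fraction``;
* a perilesional deficit gradient: the deficit probability rises toward the
  lesion border as ``severity * exp(-d / decay_length_um)``, where ``d`` is
  the distance to the border and severity varies across eyes;
* lesion growth driven by severity: the planted yearly enlargement rate is
  ``growth_intercept + growth_slope * severity + noise`` (floored at 0), and
  the follow-up mask is dilated to match it under the square-root transform;
* slab-dependent contamination: the shallowest canonical slab (11-21 um)
  receives spatially correlated dark blotches that emulate inadvertent
  RPE/Bruch's-membrane inclusion from subtle segmentation error.  The
  blotches are independent of severity, raise measured FD%, and *replace*
  the underlying capillary signal where they occur; the planted perilesional
  gradient is additionally attenuated, because the misplaced slab samples the
  wrong tissue.  Deeper slabs get contamination 0;
* duplicate grader delineations, simulated by smooth boundary jitter.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import ndtr

from .exceptions import GenerationError
from .geometry import (
    CANONICAL_SLABS,
    BinaryMask,
    EnFaceImage,
    ImageGeometry,
    SlabSpec,
)
from .rings import distance_from_lesion

__all__ = [
    "SynthConfig",
    "EyeCase",
    "generate_lesion_mask",
    "grow_lesion",
    "generate_flow_structure_pair",
    "jitter_boundary",
    "generate_eye",
    "iter_cohort",
    "generate_cohort",
]

_MOD = 2**31  # all derived seeds stay below 2^31


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic cohort.

    The defaults emulate the clinical cohort the analysis is designed for:
    31 eyes of 31 patients, median baseline lesion area 0.69 mm^2, median
    follow-up 1.31 years, and a median planted enlargement rate of
    0.05 + 0.4 * 0.30 = 0.17 mm/yr.
    """

    n_eyes: int = 31
    seed: int = 0
    geometry: ImageGeometry = field(default_factory=ImageGeometry)
    #: target deficit fraction far from the lesion
    baseline_fd_fraction: float = 0.25
    #: spatial decay of the perilesional deficit gradient (um); 300 um spans
    #: roughly the first 3-6 rings of a 100-um grid
    decay_length_um: float = 300.0
    #: median and log-sd of the across-eye lognormal severity s_i
    severity_median: float = 0.30
    severity_spread: float = 0.7
    #: linear map from severity to planted yER (mm/yr), plus residual noise
    growth_intercept_mm: float = 0.05
    growth_slope: float = 0.4
    growth_noise_sd: float = 0.035
    #: amplitude of the shallow-slab artifact; 0 disables it
    contamination_level: float = 1.0
    #: median blotch coverage per unit contamination_level
    contamination_coverage: float = 0.3
    #: severity retention in a contaminated slab is exp(-signal_loss * level)
    contamination_signal_loss: float = 2.5
    #: correlation length of the capillary texture (um)
    texture_scale_um: float = 30.0
    lesion_area_median_mm2: float = 0.69
    lesion_area_log_sd: float = 1.0
    fu_years_median: float = 1.31
    fu_years_log_sd: float = 0.06
    #: sd of the second grader's smooth boundary perturbation (um)
    grader_jitter_um: float = 12.0
    slabs: tuple[SlabSpec, ...] = CANONICAL_SLABS
    n_graders: int = 2

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError(f"n_eyes must be >= 1, got {self.n_eyes}")
        if not (0.0 <= self.baseline_fd_fraction <= 1.0):
            raise ValueError("baseline_fd_fraction must lie in [0, 1]")
        for name in ("decay_length_um", "texture_scale_um", "lesion_area_median_mm2",
                     "fu_years_median", "severity_median"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")
        if self.contamination_level < 0 or self.grader_jitter_um < 0:
            raise ValueError("contamination_level and grader_jitter_um must be >= 0")
        if self.n_graders not in (1, 2):
            raise ValueError("n_graders must be 1 or 2")


@dataclass
class EyeCase:
    """One eye's full input bundle plus the planted ground truth."""

    patient_id: str
    eye_id: str
    slabs: dict[SlabSpec, tuple[EnFaceImage, EnFaceImage]]  # slab -> (flow, structure)
    lesion_baseline: list[BinaryMask]  # one mask per grader
    lesion_followup: list[BinaryMask]
    fu_years: float
    truth: dict

    def __post_init__(self) -> None:
        for b, f in zip(self.lesion_baseline, self.lesion_followup):
            if f.area_mm2 < b.area_mm2:
                raise GenerationError("follow-up lesion smaller than baseline")


def _grf(rng: np.random.Generator, shape: tuple[int, int], sigma_px: float) -> np.ndarray:
    """Standardized Gaussian random field with correlation length ~sigma_px."""
    white = rng.standard_normal(shape)
    if sigma_px > 0:
        f = ndimage.gaussian_filter(white, sigma_px, mode="reflect")
    else:
        f = white
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 1e-12 else 1.0)


def _signed_distance_um(pixels: np.ndarray, pitch_um: float) -> np.ndarray:
    """Signed distance to the mask boundary: positive outside, negative inside."""
    outside = ndimage.distance_transform_edt(~pixels)
    inside = ndimage.distance_transform_edt(pixels)
    return (outside - inside) * pitch_um


def _match_area(field_vals: np.ndarray, target_mm2: float, px_area_mm2: float):
    """Threshold a scalar field at the level that hits a target area exactly.

    Selects the N smallest field values (N = target area in pixels), i.e. the
    sub-level set of the field closest to the target; equivalent to bisection
    on a global offset but exact to one pixel.  Ties at the threshold level
    are broken by a deterministic infinitesimal perturbation of the caller's
    field.  Returns (mask, area_mm2).
    """
    n_px = int(round(target_mm2 / px_area_mm2))
    flat = field_vals.ravel()
    if n_px <= 0 or n_px > flat.size:
        raise GenerationError(f"target area {target_mm2} mm^2 not representable on this grid")
    kth = np.partition(flat, n_px - 1)[n_px - 1]
    mask = field_vals <= kth
    # resolve residual ties at the threshold level
    excess = int(mask.sum()) - n_px
    if excess > 0:
        tie_idx = np.flatnonzero((field_vals == kth).ravel())
        drop = tie_idx[-excess:]
        m = mask.ravel()
        m[drop] = False
        mask = m.reshape(field_vals.shape)
    return mask, n_px * px_area_mm2


def generate_lesion_mask(
    geometry: ImageGeometry, target_area_mm2: float, seed: int
) -> BinaryMask:
    """A connected, irregular, centrally placed lesion blob of a given area.

    The blob is the union of 3-8 random overlapping disks, smoothed by
    morphological closing; its area is then matched to the target (within 5%,
    in practice to one pixel) by thresholding its signed-distance field,
    which acts as a global dilation/erosion radius.
    """
    if not (0 < target_area_mm2 < geometry.field_area_mm2 / 4):
        raise GenerationError(
            f"target area {target_area_mm2} mm^2 outside (0, field/4) "
            f"= (0, {geometry.field_area_mm2 / 4}) mm^2"
        )
    rng = np.random.default_rng([int(seed) % _MOD, 101])
    n = geometry.grid_size_px
    pitch_mm = geometry.pixel_pitch_um / 1000.0
    r_eq_px = math.sqrt(target_area_mm2 / math.pi) / pitch_mm
    c = (n - 1) / 2.0
    yy, xx = np.indices((n, n), dtype=np.float64)

    blob = np.zeros((n, n), dtype=bool)
    for _ in range(int(rng.integers(3, 9))):
        cy = c + rng.uniform(-0.55, 0.55) * r_eq_px
        cx = c + rng.uniform(-0.55, 0.55) * r_eq_px
        rad = max(1.5, rng.uniform(0.35, 0.75) * r_eq_px)
        blob |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    blob = ndimage.binary_closing(blob, structure=np.ones((3, 3), dtype=bool), iterations=2)
    # keep the largest connected piece so the lesion is a single focus
    labels, nlab = ndimage.label(blob)
    if nlab == 0:
        raise GenerationError("degenerate seed blob")
    if nlab > 1:
        sizes = np.bincount(labels.ravel())[1:]
        blob = labels == (1 + int(np.argmax(sizes)))

    s = _signed_distance_um(blob, geometry.pixel_pitch_um)
    # infinitesimal deterministic dither so ties on a distance contour break
    # reproducibly
    s = s + rng.uniform(0.0, 1e-6, size=s.shape)
    mask, area = _match_area(s, target_area_mm2, geometry.pixel_area_mm2)
    if abs(area - target_area_mm2) > 0.05 * target_area_mm2:
        raise GenerationError(
            f"could not reach target area {target_area_mm2} mm^2 (got {area:.4f})"
        )
    return BinaryMask(mask, geometry=geometry, label="lesion")


def grow_lesion(
    lesion: BinaryMask,
    yer_mm_per_yr: float,
    fu_years: float,
    seed: int,
    boundary_noise_um: float = 15.0,
) -> BinaryMask:
    """Follow-up lesion matching a planted enlargement rate.

    The baseline mask is dilated (with smooth angular noise on the dilation
    radius) so that sqrt(area_fu) - sqrt(area_base) = yER * FU within 2% (in
    practice to one pixel).  Growth is outward-only: the baseline is a subset
    of the result.  Raises when the required growth does not fit in the field.
    """
    if yer_mm_per_yr < 0:
        raise ValueError(f"yER must be >= 0, got {yer_mm_per_yr}")
    if fu_years <= 0:
        raise ValueError(f"follow-up must be > 0, got {fu_years}")
    if yer_mm_per_yr == 0:
        return BinaryMask(lesion.pixels.copy(), geometry=lesion.geometry, label="lesion")
    geom = lesion.geometry
    a1 = lesion.area_mm2
    target = (math.sqrt(a1) + yer_mm_per_yr * fu_years) ** 2
    if target >= geom.field_area_mm2:
        raise GenerationError("growth target exceeds the field of view")
    rng = np.random.default_rng([int(seed) % _MOD, 103])
    s = _signed_distance_um(lesion.pixels, geom.pixel_pitch_um)
    g = _grf(rng, geom.shape, 100.0 / geom.pixel_pitch_um) * boundary_noise_um
    # baseline pixels are pinned so growth is strictly outward
    f = np.where(lesion.pixels, -np.inf, s - g)
    mask, area = _match_area(f, target, geom.pixel_area_mm2)
    border = np.zeros(geom.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if (mask & border).any():
        raise GenerationError("growth pushed the lesion outside the field")
    if abs(math.sqrt(area) - math.sqrt(target)) > 0.02 * math.sqrt(target):
        raise GenerationError(
            f"could not match growth target (area {area:.3f} vs {target:.3f} mm^2)"
        )
    return BinaryMask(mask, geometry=geom, label="lesion")


def _slab_contamination_level(config: SynthConfig, slab: SlabSpec) -> float:
    # only the shallow canonical slab (inner boundary above 21 um) is
    # susceptible to RPE/BM inclusion
    return config.contamination_level if slab.inner_offset_um < 21.0 else 0.0


def generate_flow_structure_pair(
    geometry: ImageGeometry,
    config: SynthConfig,
    lesion: BinaryMask,
    severity: float,
    slab: SlabSpec,
    seed: int,
    distance_um: np.ndarray | None = None,
) -> tuple[EnFaceImage, EnFaceImage]:
    """One slab's (flow, structure) en-face pair for a given eye.

    The pair depends on the slab only through its contamination level, so two
    slabs generated with the same seed and contamination 0 are identical.
    ``distance_um`` may be supplied to reuse a precomputed lesion distance
    field.
    """
    if severity < 0:
        raise ValueError(f"severity must be >= 0, got {severity}")
    n = geometry.grid_size_px
    pitch = geometry.pixel_pitch_um
    rng = np.random.default_rng([int(seed) % _MOD, 11])

    d = distance_um if distance_um is not None else distance_from_lesion(lesion)
    level = _slab_contamination_level(config, slab)
    sev_eff = severity * math.exp(-config.contamination_signal_loss * level)
    p_def = np.clip(
        config.baseline_fd_fraction + sev_eff * np.exp(-d / config.decay_length_um),
        0.02, 0.92,
    )

    texture = _grf(rng, (n, n), config.texture_scale_um / pitch)
    deficit = ndtr(texture) < p_def
    speckle = _grf(rng, (n, n), max(0.6, 10.0 / pitch))
    flow = np.where(deficit, 0.10 + 0.04 * speckle, 0.78 + 0.08 * speckle)

    if level > 0:
        # independent stream: switching contamination off must leave the base
        # fields untouched
        crng = np.random.default_rng([int(seed) % _MOD, 13])
        coverage = min(0.85, config.contamination_coverage * level * crng.lognormal(0.0, 0.4))
        blotch = ndtr(_grf(crng, (n, n), 200.0 / pitch)) < coverage
        flow = np.where(blotch, 0.12 + 0.05 * speckle, flow)

    # smooth attenuation (vignette + slow drift) that the compensation stage
    # is meant to correct; structural image mirrors it and adds lesion
    # hypertransmission
    yy, xx = np.indices((n, n), dtype=np.float64)
    cdist = np.hypot(yy - (n - 1) / 2.0, xx - (n - 1) / 2.0) / (n / 2.0)
    alpha = np.clip(
        1.0 - 0.05 * cdist**2 + 0.04 * _grf(rng, (n, n), 500.0 / pitch), 0.7, 1.0
    )
    # soft intralesional profile, eroded before smoothing so the ramp stays
    # inside the border and plants no spurious perilesional deficit signal
    sig = max(1.0, 30.0 / pitch)
    core = ndimage.binary_erosion(lesion.pixels, iterations=int(np.ceil(2.0 * sig)))
    lesion_soft = ndimage.gaussian_filter(core.astype(np.float64), sig)
    grain = _grf(rng, (n, n), 1.0)

    flow = flow * (1.0 - 0.65 * lesion_soft) * alpha
    flow = np.clip(ndimage.gaussian_filter(flow, 0.5), 0.0, 1.0)
    structure = np.clip(0.55 * alpha + 0.35 * lesion_soft + 0.04 * grain, 0.0, 1.0)

    return (
        EnFaceImage(flow, geometry=geometry, modality="flow", slab=slab),
        EnFaceImage(structure, geometry=geometry, modality="structure", slab=slab),
    )


def jitter_boundary(
    mask: BinaryMask, jitter_um: float, seed: int, corr_length_um: float = 100.0
) -> BinaryMask:
    """Perturb a mask boundary with a smooth zero-mean normal displacement.

    Emulates a second grader's delineation of the same lesion.  With
    ``jitter_um = 0`` the mask is returned unchanged.
    """
    if jitter_um < 0:
        raise ValueError("jitter_um must be >= 0")
    if jitter_um == 0:
        return BinaryMask(mask.pixels.copy(), geometry=mask.geometry, label=mask.label)
    rng = np.random.default_rng([int(seed) % _MOD, 107])
    s = _signed_distance_um(mask.pixels, mask.geometry.pixel_pitch_um)
    g = _grf(rng, mask.geometry.shape, corr_length_um / mask.geometry.pixel_pitch_um)
    return BinaryMask(s <= g * jitter_um, geometry=mask.geometry, label=mask.label)


def _eye_seeds(config_seed: int, index: int) -> list[int]:
    ss = np.random.SeedSequence([int(config_seed) % _MOD, 7919, int(index)])
    return [int(x % _MOD) for x in ss.generate_state(12, dtype=np.uint64)]


def generate_eye(config: SynthConfig, index: int) -> EyeCase:
    """Generate the *index*-th eye of the cohort defined by *config*."""
    geom = config.geometry
    seeds = _eye_seeds(config.seed, index)
    rng = np.random.default_rng(seeds[0])

    area_cap = min(5.0, 0.9 * geom.field_area_mm2 / 4.0)
    area = float(
        np.clip(
            rng.lognormal(math.log(config.lesion_area_median_mm2), config.lesion_area_log_sd),
            0.1, area_cap,
        )
    )
    severity = float(rng.lognormal(math.log(config.severity_median), config.severity_spread))
    fu_years = float(rng.lognormal(math.log(config.fu_years_median), config.fu_years_log_sd))
    yer = max(
        0.0,
        config.growth_intercept_mm
        + config.growth_slope * severity
        + rng.normal(0.0, config.growth_noise_sd),
    )

    lesion = generate_lesion_mask(geom, area, seeds[1])
    followup = grow_lesion(lesion, yer, fu_years, seeds[2])
    baselines, followups = [lesion], [followup]
    if config.n_graders == 2:
        b2 = jitter_boundary(lesion, config.grader_jitter_um, seeds[3])
        f2 = jitter_boundary(followup, config.grader_jitter_um, seeds[4])
        f2 = BinaryMask(f2.pixels | b2.pixels, geometry=geom, label=f2.label)
        baselines.append(b2)
        followups.append(f2)

    d_um = distance_from_lesion(lesion)
    slabs: dict[SlabSpec, tuple[EnFaceImage, EnFaceImage]] = {}
    for i, slab in enumerate(config.slabs):
        slabs[slab] = generate_flow_structure_pair(
            geom, config, lesion, severity, slab,
            seed=(seeds[5] + i) % _MOD, distance_um=d_um,
        )

    return EyeCase(
        patient_id=f"P{index:03d}",
        eye_id=f"E{index:03d}",
        slabs=slabs,
        lesion_baseline=baselines,
        lesion_followup=followups,
        fu_years=fu_years,
        truth={
            "severity": severity,
            "yer_planted_mm": yer,
            "ga1_mm2": lesion.area_mm2,
            "ga2_mm2": followup.area_mm2,
            "fu_years": fu_years,
        },
    )


def iter_cohort(config: SynthConfig) -> Iterator[EyeCase]:
    """Lazily generate the cohort (one eye per patient)."""
    for i in range(config.n_eyes):
        yield generate_eye(config, i)


def generate_cohort(
    config: SynthConfig,
    slabs: Sequence[SlabSpec] | None = None,
    n_graders: int | None = None,
) -> list[EyeCase]:
    """Generate the full cohort as a list.

    ``slabs`` / ``n_graders`` override the config for callers that only need
    part of each eye (the per-eye random draws are unaffected).
    """
    if slabs is not None or n_graders is not None:
        config = replace(
            config,
            slabs=tuple(slabs) if slabs is not None else config.slabs,
            n_graders=n_graders if n_graders is not None else config.n_graders,
        )
    return list(iter_cohort(config))
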