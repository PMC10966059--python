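import dataclasses
import math

import numpy as np
import pytest

from ccfd.binarize import extract_components, fd_percent
from ccfd.exceptions import GenerationError
from ccfd.geometry import BinaryMask, ImageGeometry, SlabSpec
from ccfd.rings import build_rings, ring_fd_profile
from ccfd.stats import spearman_corr
from ccfd.synthetic import (
    SynthConfig,
    generate_cohort,
    generate_eye,
    generate_flow_structure_pair,
    generate_lesion_mask,
    grow_lesion,
    jitter_boundary,
)

GEOM = ImageGeometry(6.0, 256)
DEEP = SlabSpec(21.0, 31.0)
SHALLOW = SlabSpec(11.0, 21.0)


def small_config(**over):
    defaults = dict(geometry=GEOM, n_eyes=3, seed=7)
    defaults.update(over)
    return dataclasses.replace(SynthConfig(), **defaults)


class TestGenerateLesionMask:
    def test_hits_calibration_target_area(self):
        m = generate_lesion_mask(GEOM, 0.69, seed=3)
        assert 0.655 <= m.area_mm2 <= 0.725  # within 5% of 0.69

    def test_zero_target_rejected(self):
        with pytest.raises(GenerationError):
            generate_lesion_mask(GEOM, 0.0, seed=3)

    def test_oversized_target_rejected(self):
        with pytest.raises(GenerationError):
            generate_lesion_mask(GEOM, GEOM.field_area_mm2 / 4 + 1.0, seed=3)

    def test_deterministic_under_seed(self):
        a = generate_lesion_mask(GEOM, 0.69, seed=11)
        b = generate_lesion_mask(GEOM, 0.69, seed=11)
        assert np.array_equal(a.pixels, b.pixels)

    def test_connected_and_central(self):
        from scipy import ndimage

        m = generate_lesion_mask(GEOM, 1.5, seed=5)
        _, n = ndimage.label(m.pixels, structure=np.ones((3, 3)))
        assert n == 1
        com = ndimage.center_of_mass(m.pixels)
        assert abs(com[0] - 127.5) < 30 and abs(com[1] - 127.5) < 30


class TestGrowLesion:
    def test_zero_rate_returns_baseline(self):
        base = generate_lesion_mask(GEOM, 1.0, seed=1)
        fu = grow_lesion(base, 0.0, 1.5, seed=2)
        assert np.array_equal(fu.pixels, base.pixels)

    def test_sqrt_transform_algebra(self):
        base = generate_lesion_mask(GEOM, 1.0, seed=1)
        fu = grow_lesion(base, 0.5, 2.0, seed=2)
        target = (math.sqrt(base.area_mm2) + 1.0) ** 2
        assert fu.area_mm2 == pytest.approx(target, rel=0.02)

    def test_calibration_case(self):
        # baseline 0.69 mm^2, yER 0.17, FU 1.31 yr -> (sqrt(.69)+.17*1.31)^2 = 1.1096
        base = generate_lesion_mask(GEOM, 0.69, seed=4)
        fu = grow_lesion(base, 0.17, 1.31, seed=5)
        target = (math.sqrt(base.area_mm2) + 0.17 * 1.31) ** 2
        assert target == pytest.approx(1.11, abs=0.02)
        assert fu.area_mm2 == pytest.approx(target, rel=0.02)

    def test_growth_is_outward_only(self):
        base = generate_lesion_mask(GEOM, 0.69, seed=6)
        fu = grow_lesion(base, 0.4, 2.0, seed=7)
        assert np.all(fu.pixels[base.pixels])

    def test_growth_outside_field_rejected(self):
        base = generate_lesion_mask(GEOM, 4.0, seed=8)
        # sqrt(4) + 1.8*2 = 5.6 -> 31.4 mm^2: fits in 36 mm^2 of field area
        # but its equivalent radius (3.16 mm) exceeds the half-width
        with pytest.raises(GenerationError):
            grow_lesion(base, 1.8, 2.0, seed=9)
        # and a target beyond the whole field is rejected outright
        with pytest.raises(GenerationError):
            grow_lesion(base, 2.0, 2.0, seed=9)


class TestFlowStructurePair:
    def test_no_gradient_when_severity_zero(self):
        # single-eye ring FD% carries ~3-4 pp of texture sampling noise at
        # these ring sizes, so the flatness check averages over several eyes
        from ccfd.compensation import compensate_flow
        from ccfd.binarize import phansalkar_threshold

        geom = ImageGeometry(6.0, 512)
        cfg = small_config(geometry=geom, contamination_level=0.0)
        profiles = []
        for seed in range(24):
            lesion = generate_lesion_mask(geom, 0.69, seed=500 + seed)
            flow, structure = generate_flow_structure_pair(
                geom, cfg, lesion, severity=0.0, slab=DEEP, seed=900 + seed
            )
            comp = compensate_flow(flow, structure)
            dm = extract_components(phansalkar_threshold(comp))
            rings = build_rings(lesion, 100.0, 10)
            profiles.append(ring_fd_profile(dm, rings))
        mean_profile = np.mean(np.asarray(profiles, dtype=float), axis=0)
        far_field = np.mean(mean_profile[6:])
        for fd in mean_profile[:6]:
            assert abs(fd - far_field) < 3.0

    def test_slab_independence_without_contamination(self):
        cfg = small_config(contamination_level=0.0)
        lesion = generate_lesion_mask(GEOM, 0.69, seed=2)
        out = [
            generate_flow_structure_pair(GEOM, cfg, lesion, 0.3, slab, seed=9)
            for slab in (SHALLOW, DEEP)
        ]
        assert np.array_equal(out[0][0].pixels, out[1][0].pixels)
        assert np.array_equal(out[0][1].pixels, out[1][1].pixels)

    def test_contamination_raises_shallow_fd(self):
        cfg = small_config()
        field = BinaryMask(np.ones(GEOM.shape, dtype=bool), geometry=GEOM)
        diffs = []
        for seed in range(20):
            lesion = generate_lesion_mask(GEOM, 0.69, seed=100 + seed)
            fds = {}
            for slab in (SHALLOW, DEEP):
                flow, structure = generate_flow_structure_pair(
                    GEOM, cfg, lesion, 0.3, slab, seed=200 + seed
                )
                from ccfd.compensation import compensate_flow
                from ccfd.binarize import phansalkar_threshold

                dm = extract_components(phansalkar_threshold(compensate_flow(flow, structure)))
                fds[slab.name] = fd_percent(dm, field)
            diffs.append(fds[SHALLOW.name] - fds[DEEP.name])
        assert np.mean(diffs) > 0

    def test_lesion_interior_dark_flow_bright_structure(self):
        cfg = small_config(contamination_level=0.0)
        lesion = generate_lesion_mask(GEOM, 1.5, seed=2)
        flow, structure = generate_flow_structure_pair(GEOM, cfg, lesion, 0.3, DEEP, seed=3)
        from scipy import ndimage

        core = ndimage.binary_erosion(lesion.pixels, iterations=3)
        outside = ~ndimage.binary_dilation(lesion.pixels, iterations=10)
        assert flow.pixels[core].mean() < flow.pixels[outside].mean()
        assert structure.pixels[core].mean() > structure.pixels[outside].mean()


class TestJitterBoundary:
    def test_zero_jitter_is_identity(self):
        m = generate_lesion_mask(GEOM, 0.69, seed=1)
        j = jitter_boundary(m, 0.0, seed=2)
        assert np.array_equal(j.pixels, m.pixels)

    def test_jitter_perturbs_boundary_slightly(self):
        # at 512 px the 11.7 um pitch resolves the 12 um jitter
        m = generate_lesion_mask(ImageGeometry(6.0, 512), 0.69, seed=1)
        j = jitter_boundary(m, 12.0, seed=2)
        sym_diff = np.logical_xor(j.pixels, m.pixels).sum()
        assert 0 < sym_diff < 0.2 * m.count
        assert j.area_mm2 == pytest.approx(m.area_mm2, rel=0.1)


class TestGenerateCohort:
    def test_deterministic_byte_for_byte(self):
        cfg = small_config(n_eyes=2)
        c1 = generate_cohort(cfg)
        c2 = generate_cohort(cfg)
        for e1, e2 in zip(c1, c2):
            assert e1.fu_years == e2.fu_years
            assert e1.truth == e2.truth
            for s in cfg.slabs:
                assert np.array_equal(e1.slabs[s][0].pixels, e2.slabs[s][0].pixels)
            for m1, m2 in zip(e1.lesion_baseline, e2.lesion_baseline):
                assert np.array_equal(m1.pixels, m2.pixels)

    def test_growth_never_shrinks_and_baseline_is_subset(self):
        for eye in generate_cohort(small_config(n_eyes=4, seed=21), n_graders=1):
            b, f = eye.lesion_baseline[0], eye.lesion_followup[0]
            assert f.area_mm2 >= b.area_mm2
            assert np.all(f.pixels[b.pixels])

    def test_invalid_cohort_size_rejected(self):
        with pytest.raises(ValueError):
            small_config(n_eyes=0)

    def test_planted_link_between_severity_and_border_deficit(self):
        # without contamination the rank correlation between per-eye severity
        # and measured near-border FD% should be strong (> 0.8)
        from ccfd.pipeline import analyze_cohort

        cfg = small_config(n_eyes=15, seed=31, contamination_level=0.0)
        cohort = generate_cohort(cfg, slabs=(DEEP,), n_graders=1)
        res = analyze_cohort(cohort)
        ring1 = (
            res.ring_fd.query("ring == 1").set_index("eye")["fd_pct"]
        )
        sev = {e.eye_id: e.truth["severity"] for e in cohort}
        rho, _ = spearman_corr(
            [sev[e] for e in ring1.index], ring1.values
        )
        assert rho > 0.8

    def test_null_growth_slope_decouples_severity_from_yer(self):
        cfg = small_config(n_eyes=40, seed=13, growth_slope=0.0, growth_noise_sd=0.05)
        eyes = [generate_eye(cfg, i) for i in range(cfg.n_eyes)]
        sev = [e.truth["severity"] for e in eyes]
        yer = [e.truth["yer_planted_mm"] for e in eyes]
        rho, p = spearman_corr(sev, yer)
        assert abs(rho) < 0.45
        assert p > 0.01
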