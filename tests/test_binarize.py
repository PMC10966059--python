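import math

import numpy as np
import pytest

from ccfd.binarize import (
    PhansalkarParams,
    extract_components,
    fd_percent,
    filter_small_deficits,
    phansalkar_threshold,
)
from ccfd.exceptions import EmptyRegionError, NormalizationError
from ccfd.geometry import ImageGeometry

from _oracles import brute_phansalkar_threshold, rasterize_disk
from conftest import make_image, make_mask


def _threshold_map(pix, params):
    """Recompute the fast path's threshold map for comparison with the oracle."""
    from scipy import ndimage

    foot = params.footprint().astype(float)
    w = foot / foot.sum()
    m = ndimage.correlate(pix, w, mode="reflect")
    m2 = ndimage.correlate(pix * pix, w, mode="reflect")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    return m * (1.0 + params.p * np.exp(-params.q * m) + params.k * ((s / params.r) - 1.0))


class TestPhansalkarThreshold:
    def test_constant_half_image_has_no_deficits(self):
        # m = 0.5, s = 0: t = 0.5*(1 + 2*exp(-5) + 0.25*(0/0.5 - 1)) = 0.381738...
        img = make_image(np.full((64, 64), 0.5))
        t = _threshold_map(img.pixels, PhansalkarParams())
        expected = 0.5 * (1.0 + 2.0 * math.exp(-5.0) - 0.25)
        assert np.allclose(t, expected)
        assert expected == pytest.approx(0.381738, abs=1e-6)
        assert not phansalkar_threshold(img).pixels.any()

    def test_constant_bright_image_has_no_deficits(self):
        # m = 1, s = 0: t = 1 + 2*exp(-10) - 0.25 = 0.750091
        img = make_image(np.ones((64, 64)))
        t = _threshold_map(img.pixels, PhansalkarParams())
        assert np.allclose(t, 1.0 + 2.0 * math.exp(-10.0) - 0.25)
        assert not phansalkar_threshold(img).pixels.any()

    @pytest.mark.parametrize("window", ["circular", "square"])
    def test_matches_per_pixel_window_oracle(self, rng, window):
        params = PhansalkarParams(window=window)
        for _ in range(20):
            pix = rng.random((64, 64))
            fast_t = _threshold_map(pix, params)
            slow_t = brute_phansalkar_threshold(
                pix, params.radius_px, params.k, params.r, params.p, params.q, window
            )
            assert np.max(np.abs(fast_t - slow_t)) < 1e-6
            assert np.array_equal(
                phansalkar_threshold(make_image(pix), params).pixels, pix < slow_t
            )

    def test_dark_pools_in_bright_field_are_deficits(self, rng):
        pix = np.full((64, 64), 0.8)
        pix[20:30, 20:30] = 0.1
        mask = phansalkar_threshold(make_image(pix)).pixels
        assert mask[22:28, 22:28].all()  # interior of the pool
        assert not mask[:10, :10].any()  # uniform bright region

    def test_unnormalized_input_rejected(self):
        with pytest.raises(NormalizationError):
            phansalkar_threshold(make_image(np.full((64, 64), 2.0)))


class TestExtractComponents:
    def test_empty_mask_has_no_components(self):
        dm = extract_components(make_mask(np.zeros((64, 64), dtype=bool)))
        assert dm.n_components == 0

    def test_two_disjoint_blobs(self):
        pix = np.zeros((64, 64), dtype=bool)
        pix[5:10, 5] = True  # 5 px line
        pix[40, 40:45] = True  # 5 px line
        dm = extract_components(make_mask(pix))
        assert dm.n_components == 2
        assert sorted(c.pixel_count for c in dm.components) == [5, 5]

    def test_diagonal_touching_is_one_component(self):
        pix = np.zeros((64, 64), dtype=bool)
        pix[10, 10] = pix[11, 11] = True  # 8-connectivity joins diagonals
        dm = extract_components(make_mask(pix))
        assert dm.n_components == 1

    def test_equivalent_diameter_of_rasterized_disk(self):
        geom = ImageGeometry(6.0, 1024)  # pitch 5.859 um
        r_px = 15.0 / geom.pixel_pitch_um  # true diameter 30 um
        disk = rasterize_disk(64, 31.5, 31.5, r_px)
        # embed in a full-size-compatible small geometry with the same pitch
        geom64 = ImageGeometry(6.0 * 64 / 1024, 64)
        dm = extract_components(make_mask(disk, geom64))
        assert dm.n_components == 1
        assert dm.components[0].equivalent_diameter_um == pytest.approx(30.0, rel=0.10)


class TestFilterSmallDeficits:
    @staticmethod
    def _planted(geom, diameters_um):
        n = geom.grid_size_px
        pix = np.zeros((n, n), dtype=bool)
        for i, d in enumerate(diameters_um):
            r_px = (d / 2.0) / geom.pixel_pitch_um
            cx = (i + 1) * n / (len(diameters_um) + 1)
            pix |= rasterize_disk(n, n / 2.0, cx, r_px)
        return make_mask(pix, geom)

    def test_straddling_cutoff_keeps_only_large_disk(self):
        geom = ImageGeometry(6.0 * 128 / 1024, 128)  # standard 5.86 um pitch
        dm = extract_components(self._planted(geom, [20.0, 30.0]))
        assert dm.n_components == 2
        kept = filter_small_deficits(dm, 24.0)
        assert kept.n_components == 1
        assert kept.components[0].equivalent_diameter_um >= 24.0

    def test_noop_when_all_components_large(self):
        geom = ImageGeometry(6.0 * 128 / 1024, 128)
        dm = extract_components(self._planted(geom, [30.0, 40.0]))
        kept = filter_small_deficits(dm, 24.0)
        assert np.array_equal(kept.mask.pixels, dm.mask.pixels)

    def test_zero_cutoff_disables_filter(self, rng):
        dm = extract_components(make_mask(rng.random((64, 64)) < 0.2))
        kept = filter_small_deficits(dm, 0.0)
        assert np.array_equal(kept.mask.pixels, dm.mask.pixels)
        assert kept.n_components == dm.n_components

    def test_raising_cutoff_never_increases_fd(self, rng):
        geom = ImageGeometry(6.0, 128)
        dm = extract_components(make_mask(rng.random((128, 128)) < 0.3, geom))
        region = make_mask(np.ones((128, 128), dtype=bool), geom)
        fds = [
            fd_percent(filter_small_deficits(dm, cut), region)
            for cut in [0.0, 24.0, 50.0, 100.0]
        ]
        assert all(a >= b for a, b in zip(fds, fds[1:]))


class TestFdPercent:
    def test_extremes_and_direct_count(self, rng):
        geom = ImageGeometry(6.0, 64)
        region = np.zeros((64, 64), dtype=bool)
        region[:10, :10] = True
        deficit = np.zeros((64, 64), dtype=bool)
        assert fd_percent(make_mask(deficit, geom), make_mask(region, geom)) == 0.0
        deficit[:10, :10] = True
        assert fd_percent(make_mask(deficit, geom), make_mask(region, geom)) == 100.0
        deficit[:, :] = False
        flat = rng.choice(100, size=37, replace=False)
        deficit[flat // 10, flat % 10] = True
        assert fd_percent(make_mask(deficit, geom), make_mask(region, geom)) == 37.0

    def test_empty_region_is_an_error_not_zero(self):
        geom = ImageGeometry(6.0, 64)
        deficit = make_mask(np.ones((64, 64), dtype=bool), geom)
        with pytest.raises(EmptyRegionError):
            fd_percent(deficit, make_mask(np.zeros((64, 64), dtype=bool), geom))

    def test_monotone_in_deficit_pixels(self, rng):
        geom = ImageGeometry(6.0, 64)
        region = make_mask(rng.random((64, 64)) < 0.5, geom)
        d1 = rng.random((64, 64)) < 0.2
        d2 = d1 | (rng.random((64, 64)) < 0.2)
        assert fd_percent(make_mask(d2, geom), region) >= fd_percent(make_mask(d1, geom), region)
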