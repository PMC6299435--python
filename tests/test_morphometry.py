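"""Distance transform, thickness, areas, diameters, stack summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortamorph import PhantomSpec, generate_phantom
from aortamorph import morphometry as mm
from aortamorph.geometry import contour_radius, smooth_radius_periodic


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """O(n^2) nearest-background search; the independent oracle."""
    mask = np.asarray(mask, bool)
    out = np.zeros(mask.shape, dtype=float)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        return np.full(mask.shape, np.inf)
    for r, c in np.argwhere(mask):
        d = np.hypot(bg[:, 0] - r, bg[:, 1] - c)
        out[r, c] = d.min()
    return out


class TestEuclideanDistanceTransform:
    def test_single_foreground_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        assert mm.euclidean_distance_transform(mask)[2, 2] == 1.0

    def test_all_background_is_zero_map(self):
        assert not mm.euclidean_distance_transform(np.zeros((4, 4), bool)).any()

    def test_solid_disk_max_is_inradius(self):
        yy, xx = np.mgrid[:64, :64]
        mask = np.hypot(yy - 31.5, xx - 31.5) <= 20.0
        assert mm.euclidean_distance_transform(mask).max() == pytest.approx(20.0, abs=0.75)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_exactly(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((16, 16)) < 0.4
        assert np.array_equal(
            mm.euclidean_distance_transform(mask), brute_force_edt(mask)
        )


@pytest.fixture(scope="module")
def annulus_setup(small_phantom, small_run):
    z = sorted(small_run.segmentations)[0]
    return small_run.segmentations[z], small_phantom[1]


class TestMediaThickness:
    def test_constant_band_recovered(self, annulus_setup):
        seg, truth = annulus_setup
        r = contour_radius(seg.lumen_contour, seg.lumen_centroid, 720)
        rs = smooth_radius_periodic(r)
        td = mm.media_thickness(seg.media_mask, seg.lumen_centroid, rs, 1.1)
        true_um = truth.per_slice.media_thickness_um[0]
        assert td.mean_um == pytest.approx(true_um, abs=0.6)
        assert td.sd_um < 1.0
        assert td.n_samples == 720
        assert td.n_dropped == 0

    def test_fitted_mean_within_sample_range(self, annulus_setup):
        seg, _ = annulus_setup
        r = contour_radius(seg.lumen_contour, seg.lumen_centroid, 720)
        rs = smooth_radius_periodic(r)
        td = mm.media_thickness(seg.media_mask, seg.lumen_centroid, rs, 1.1)
        assert td.samples_um.min() - 1.0 <= td.mean_um <= td.samples_um.max() + 1.0

    def test_degenerate_identical_samples(self):
        # synthetic thin band: all rays measure the same depth
        mask = np.zeros((64, 64), bool)
        yy, xx = np.mgrid[:64, :64]
        rho = np.hypot(yy - 31.5, xx - 31.5)
        mask[(rho >= 20) & (rho <= 26)] = True
        r = np.full(360, 20.0)
        td = mm.media_thickness(mask, np.array([31.5, 31.5]), r, 1.0)
        bin_width = np.diff(td.bin_edges).max() if len(td.bin_edges) > 1 else 1.0
        assert td.sd_um <= max(bin_width, 1.0)


class TestAreasAndFractions:
    def test_pixel_count_times_voxel_area(self):
        mask = np.zeros((50, 50), bool)
        mask.flat[:1000] = True
        assert mm.cross_sectional_area(mask, 1.1) == pytest.approx(1210.0)

    def test_empty_mask_zero_area(self):
        assert mm.cross_sectional_area(np.zeros((8, 8), bool), 1.1) == 0.0

    def test_lamellae_equal_media_gives_100pct(self):
        m = np.ones((10, 10), bool)
        pct, lam, inter = mm.lamellae_fraction(m, m)
        assert pct == 100.0 and inter == 0.0

    def test_empty_lamellae_zero_pct(self):
        m = np.ones((10, 10), bool)
        pct, lam, inter = mm.lamellae_fraction(np.zeros_like(m), m, 2.0)
        assert pct == 0.0 and inter == m.sum() * 4.0

    def test_subset_violation_rejected(self):
        m = np.zeros((10, 10), bool)
        m[2:5, 2:5] = True
        lam = np.zeros_like(m)
        lam[0, 0] = True
        with pytest.raises(ValueError, match="subset"):
            mm.lamellae_fraction(lam, m)

    def test_exact_partition(self, small_run):
        for seg in small_run.segmentations.values():
            pct, lam, inter = mm.lamellae_fraction(seg.lamellae_mask, seg.media_mask, 1.1)
            n_lam = seg.lamellae_mask.sum()
            n_med = seg.media_mask.sum()
            assert lam + inter == pytest.approx(n_med * 1.1**2, rel=1e-12)
            assert pct == 100.0 * n_lam / n_med


def _ellipse_contour(a, b, n=256, center=(100.0, 100.0), phase=0.3):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rows = center[0] + b * np.sin(t + phase)
    cols = center[1] + a * np.cos(t + phase)
    return np.column_stack([rows, cols])


class TestLumenDiameter:
    def test_circle(self):
        d, params = mm.lumen_diameter(_ellipse_contour(100.0, 100.0), 1.0)
        assert d == pytest.approx(200.0, abs=0.5)

    def test_ellipse_mean_of_axes(self):
        d, params = mm.lumen_diameter(_ellipse_contour(100.0, 60.0), 1.0)
        assert d == pytest.approx(160.0, abs=0.5)
        assert params["semi_major_px"] == pytest.approx(100.0, abs=0.5)
        assert params["semi_minor_px"] == pytest.approx(60.0, abs=0.5)

    def test_wrinkled_circle_within_2pct(self):
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        r = 100.0 + 5.0 * np.sin(12 * t)
        contour = np.column_stack([100 + r * np.sin(t), 100 + r * np.cos(t)])
        d, _ = mm.lumen_diameter(contour, 1.0)
        assert d == pytest.approx(200.0, rel=0.02)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 10, 8), np.linspace(0, 10, 8)])
        with pytest.raises(ValueError):
            mm.lumen_diameter(pts, 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 6"):
            mm.lumen_diameter(np.zeros((5, 2)), 1.0)


class TestScaleEquivariance:
    def test_doubling_voxel_scales_lengths_and_areas(self, annulus_setup):
        seg, _ = annulus_setup
        d1, _ = mm.lumen_diameter(seg.lumen_contour, 1.1)
        d2, _ = mm.lumen_diameter(seg.lumen_contour, 2.2)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)
        a1 = mm.cross_sectional_area(seg.media_mask, 1.1)
        a2 = mm.cross_sectional_area(seg.media_mask, 2.2)
        assert a2 == pytest.approx(4 * a1, rel=1e-12)


class TestSummarize:
    def test_constant_phantom_zero_sd(self, small_run):
        s = small_run.summary
        assert (s.sds < 0.5).all()

    def test_single_record_window(self, small_run):
        one = [small_run.records[0]]
        s = mm.summarize_stack(one)
        assert s.n_slices == 1
        assert (s.sds == 0.0).all()
        assert s.means["lumen_diameter_um"] == small_run.records[0].lumen_diameter_um

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mm.summarize_stack([])
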