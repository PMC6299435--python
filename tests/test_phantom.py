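"""Phantom generator: analytic truth, rendering fidelity, determinism."""

import math

import numpy as np
import pytest
from skimage import measure

from aortamorph import (
    BreakSpec,
    DilationSpec,
    PhantomSpec,
    analytic_morphometry,
    generate_phantom,
)
from aortamorph.phantom import _band_area, _slice_geometry


class TestSpecValidation:
    def test_wall_thinner_than_lamellar_stack_rejected(self):
        spec = PhantomSpec(n_lamellae=5, lamella_thickness_px=10.0, wall_thickness_px=40.0)
        with pytest.raises(ValueError, match="wall too thin"):
            spec.validate()

    def test_vessel_exceeding_slice_bounds_rejected(self):
        spec = PhantomSpec(slice_shape=(256, 256), lumen_radius_px=120.0)
        with pytest.raises(ValueError, match="exceeds slice bounds"):
            spec.validate()

    def test_contrast_ordering_enforced(self):
        spec = PhantomSpec(grey_lamella=100.0, grey_interlamellar=200.0)
        with pytest.raises(ValueError, match="contrast ordering"):
            spec.validate()


class TestAnalyticMorphometry:
    def test_unwrinkled_diameter_is_twice_radius(self):
        spec = PhantomSpec(
            n_slices=4, lumen_radius_px=100.0, wall_thickness_px=40.0, voxel_size_um=1.0
        )
        truth = analytic_morphometry(spec)
        assert np.allclose(truth.per_slice.lumen_diameter_um, 200.0)

    def test_dilation_peak_diameter(self):
        spec = PhantomSpec(
            n_slices=64,
            lumen_radius_px=100.0,
            voxel_size_um=1.0,
            slice_shape=(640, 640),
            dilation=DilationSpec(start=40, end=60, max_scale=1.5),
        )
        truth = analytic_morphometry(spec)
        assert truth.per_slice.lumen_diameter_um.max() == pytest.approx(300.0)
        assert truth.per_slice.lumen_diameter_um[:40].max() == pytest.approx(200.0)

    def test_full_wall_media_annulus_area(self):
        # media spanning the whole 40 px wall of an r=100 annulus
        spec = PhantomSpec(
            n_slices=1,
            lumen_radius_px=100.0,
            wall_thickness_px=40.0,
            media_fraction=1.0,
            n_lamellae=3,
            lamella_thickness_px=4.0,
            voxel_size_um=1.0,
        )
        truth = analytic_morphometry(spec)
        assert truth.per_slice.media_area_um2[0] == pytest.approx(
            math.pi * (140.0**2 - 100.0**2), rel=1e-9
        )
        # 3 lamellae of 4 px, symmetric about the mid-wall: exactly 30 %
        assert truth.per_slice.lamellae_pct[0] == pytest.approx(30.0, abs=1e-9)

    def test_quadrature_matches_closed_form_for_circle(self):
        rho = lambda theta: np.full_like(theta, 100.0)
        area = _band_area(rho, 0.0, 40.0)
        assert area == pytest.approx(math.pi * (140.0**2 - 100.0**2), rel=1e-9)

    def test_partition_exact(self):
        spec = PhantomSpec(n_slices=3, wrinkle_amplitude_px=4.0, wrinkle_frequency=9)
        truth = analytic_morphometry(spec)
        assert np.allclose(
            truth.per_slice.lamellae_area_um2 + truth.per_slice.interlamellar_area_um2,
            truth.per_slice.media_area_um2,
            rtol=1e-12,
        )
        assert (truth.per_slice.lamellae_pct.between(0, 100)).all()


class TestRendering:
    def test_identical_spec_and_seed_bit_identical(self):
        spec = PhantomSpec(
            n_slices=3, slice_shape=(256, 256), lumen_radius_px=50.0,
            wall_thickness_px=20.0, lamella_thickness_px=1.6, noise_sigma=400.0, seed=7,
        )
        g1, _ = generate_phantom(spec)
        g2, _ = generate_phantom(spec)
        assert g1.data.tobytes() == g2.data.tobytes()

    def test_mask_mass_matches_analytic_area_within_perimeter(self, small_phantom):
        grid, truth = small_phantom
        for z in (0, 8):
            n_px = truth.media_masks[z].sum()
            area_px = truth.per_slice.media_area_um2[z] / truth.voxel_size_um**2
            r_out = truth.per_slice.lumen_semi_axis_row_px[z] + 0.85 * 24.0
            perimeter = 2 * math.pi * (truth.per_slice.lumen_semi_axis_row_px[z] + r_out)
            assert abs(n_px - area_px) <= perimeter

    def test_contrast_ordering_of_rendered_pixels(self, small_phantom):
        grid, _ = small_phantom  # noise-free
        img = grid.data[0]
        spec_max = 50000.0
        spec_min = 15000.0
        assert img.min() >= spec_min - 0.5
        assert img.max() <= spec_max + 0.5

    def test_wrinkled_boundary_traces_generating_formula(self, wrinkled_phantom):
        """Subpixel contour of the rendered lumen boundary deviates < 1 px
        RMS from r(theta) = 100 + 5 sin(12 theta)."""
        spec, (grid, truth) = wrinkled_phantom
        img = grid.data[0]
        level = 0.5 * (15000.0 + 30000.0)
        contours = measure.find_contours(img.astype(float), level)
        c = np.array([255.5, 255.5])
        # the lumen boundary is the level contour whose mean radius is ~100
        radii = [np.hypot(*(k - c).T) for k in contours]
        idx = int(np.argmin([abs(rr.mean() - 100.0) for rr in radii]))
        r, contour = radii[idx], contours[idx]
        theta = np.arctan2(contour[:, 0] - c[0], contour[:, 1] - c[1])
        model = 100.0 + 5.0 * np.sin(12 * theta)
        rms = np.sqrt(np.mean((r - model) ** 2))
        assert rms < 1.0

    def test_break_darkens_affected_lamella_only(self):
        spec = PhantomSpec(
            n_slices=3,
            slice_shape=(320, 320),
            lumen_radius_px=60.0,
            wall_thickness_px=24.0,
            n_lamellae=4,
            lamella_thickness_px=2.0,
            breaks=(BreakSpec(0, 2, 60, 120, (1,)),),
        )
        _, truth = generate_phantom(spec)
        clean = generate_phantom(
            PhantomSpec(
                n_slices=3, slice_shape=(320, 320), lumen_radius_px=60.0,
                wall_thickness_px=24.0, n_lamellae=4, lamella_thickness_px=2.0,
            )
        )[1]
        lost = clean.lamellae_masks[1].sum() - truth.lamellae_masks[1].sum()
        # one ring over 60 degrees of arc
        assert lost > 0
        expected = clean.lamellae_masks[1].sum() / 4 * (60.0 / 360.0)
        assert lost == pytest.approx(expected, rel=0.25)
        # analytic truth reflects the same loss
        assert truth.per_slice.lamellae_pct[1] < clean.per_slice.lamellae_pct[1]

    def test_tilted_slice_is_the_analytic_oblique_ellipse(self):
        spec = PhantomSpec(
            n_slices=9, slice_shape=(384, 384), lumen_radius_px=70.0,
            wall_thickness_px=28.0, lamella_thickness_px=2.0, axis_tilt_deg=10.0,
        )
        _, truth = generate_phantom(spec)
        g = _slice_geometry(spec, 4)
        # in-plane column semi-axis is stretched by sec(tilt)
        assert g.rx / g.cos_tilt == pytest.approx(
            70.0 / math.cos(math.radians(10.0)), rel=1e-12
        )
        # centre drifts by tan(tilt) px per slice
        drift = (
            truth.per_slice.center_col.iloc[-1] - truth.per_slice.center_col.iloc[0]
        ) / 8.0
        assert drift == pytest.approx(math.tan(math.radians(10.0)), rel=1e-9)
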