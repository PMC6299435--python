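"""Wall/lumen/media/lamellae segmentation and the watershed fallback."""

import copy
import math

import numpy as np
import pytest

from aortamorph import BreakSpec, DilationSpec, PhantomSpec, PipelineConfig, generate_phantom
from aortamorph import segmentation as sg
from conftest import dice


@pytest.fixture(scope="module")
def clean_slice(small_phantom):
    grid, truth = small_phantom
    return grid.data[0], truth


class TestSegmentWall:
    def test_dice_against_truth(self, clean_slice, small_config):
        img, truth = clean_slice
        wall = sg.segment_wall(img, smooth_disk_px=small_config.smooth_disk_px)
        assert dice(wall, truth.wall_masks[0]) >= 0.98

    def test_uniform_slice_raises_empty(self):
        with pytest.raises(sg.EmptySliceError):
            sg.segment_wall(np.full((64, 64), 123.0, np.float32))

    def test_exclusion_mask_removes_artefact(self, clean_slice):
        img, truth = clean_slice
        dirty = img.copy()
        dirty[8:20, 8:20] = 50000.0  # bright dust speck outside the vessel
        excl = np.zeros_like(dirty, dtype=bool)
        excl[5:23, 5:23] = True
        wall_clean = sg.segment_wall(img)
        wall_masked = sg.segment_wall(dirty, exclusion_mask=excl)
        assert np.array_equal(wall_clean, wall_masked)

    def test_intensity_rescale_invariance(self, clean_slice):
        img, _ = clean_slice
        wall = sg.segment_wall(img)
        wall_scaled = sg.segment_wall(img * 0.31 + 1234.0)
        assert np.array_equal(wall, wall_scaled)


class TestSegmentLumen:
    def test_centroid_on_centerline(self, clean_slice, small_phantom):
        img, truth = clean_slice
        wall = sg.segment_wall(img)
        lumen, contour = sg.segment_lumen(wall)
        rr, cc = np.nonzero(lumen)
        assert abs(rr.mean() - truth.centerline[0, 1]) < 0.5
        assert abs(cc.mean() - truth.centerline[0, 2]) < 0.5
        assert dice(lumen, small_phantom[1].lumen_masks[0]) >= 0.98

    def test_gap_in_wall_raises_open_wall(self, clean_slice):
        img, _ = clean_slice
        wall = sg.segment_wall(img)
        wall[155:165, :] = False  # cut a channel through the whole mask
        with pytest.raises(sg.OpenWallError):
            sg.segment_lumen(wall)

    def test_wrinkled_contour_follows_generating_formula(self, wrinkled_phantom):
        spec, (grid, truth) = wrinkled_phantom
        wall = sg.segment_wall(grid.data[0])
        lumen, contour = sg.segment_lumen(wall)
        c = np.array([255.5, 255.5])
        d = contour - c
        r = np.hypot(d[:, 0], d[:, 1])
        theta = np.arctan2(d[:, 0], d[:, 1])
        model = 100.0 + 5.0 * np.sin(12 * theta)
        assert np.sqrt(np.mean((r - model) ** 2)) < 1.0


def _annulus(shape, center, r_in, r_out_fn):
    rows = np.arange(shape[0])[:, None] - center[0]
    cols = np.arange(shape[1])[None, :] - center[1]
    rho = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    r_out = r_out_fn(theta)
    wall = (rho >= r_in) & (rho <= r_out)
    lumen = rho < r_in
    return wall, lumen


class TestMediaAdventitiaLimit:
    def test_constant_annulus_rule(self):
        """Inner r=100, outer r=140: media outer radius 100 + 20 + round(0.35*40)."""
        wall, lumen = _annulus((320, 320), (159.5, 159.5), 100.0, lambda t: np.full_like(t, 140.0))
        media, contour, radius, min_t = sg.media_adventitia_limit(wall, lumen)
        assert min_t == pytest.approx(40.0, abs=1.0)
        expected = 100.0 + 20.0 + round(0.35 * min_t)
        assert np.mean(radius) == pytest.approx(expected, abs=1.0)

    def test_varying_thickness_uses_minimum(self):
        """Thickness varying 40 -> 60 px: the dilation radius comes from the
        minimum, so media outer radius = midline + 14 everywhere."""
        r_out_fn = lambda t: 140.0 + 20.0 * (1.0 + np.cos(t)) / 2.0
        wall, lumen = _annulus((360, 360), (179.5, 179.5), 100.0, r_out_fn)
        media, contour, radius, min_t = sg.media_adventitia_limit(wall, lumen)
        assert min_t == pytest.approx(40.0, abs=1.0)
        k = len(radius)
        theta = np.arange(k) * 2 * np.pi / k
        midline = (100.0 + r_out_fn(theta)) / 2.0
        expected = midline + round(0.35 * min_t)
        # away from the spline's discretisation the rule holds within 1 px
        assert np.percentile(np.abs(radius - expected), 90) <= 1.5
        assert np.mean(radius - expected) == pytest.approx(0.0, abs=1.0)

    def test_media_inside_wall_adventitia_nonempty(self, small_run):
        for z, seg in small_run.segmentations.items():
            assert not np.any(seg.media_mask & ~seg.wall_mask)
            assert seg.adventitia_mask.any()

    def test_too_thin_wall_rejected(self):
        wall, lumen = _annulus((64, 64), (31.5, 31.5), 20.0, lambda t: np.full_like(t, 22.0))
        with pytest.raises(sg.WallTooThinError):
            sg.media_adventitia_limit(wall, lumen)


class TestSegmentLamellae:
    def test_recovered_ring_count_close_to_truth(self):
        # three well-separated 4-px rings spanning the full wall
        spec = PhantomSpec(
            n_slices=1, slice_shape=(384, 384), lumen_radius_px=70.0,
            wall_thickness_px=36.0, media_fraction=1.0, n_lamellae=3,
            lamella_thickness_px=4.0,
        )
        grid, truth = generate_phantom(spec)
        lam = sg.segment_lamellae(grid.data[0], truth.media_masks[0])
        n_true = truth.lamellae_masks[0].sum()
        assert lam.sum() == pytest.approx(n_true, rel=0.05)

    def test_uniform_media_raises_no_contrast(self):
        img = np.full((64, 64), 30000.0, np.float32)
        media = np.zeros((64, 64), bool)
        media[20:40, 20:40] = True
        with pytest.raises(sg.NoContrastError):
            sg.segment_lamellae(img, media)

    def test_subset_of_media_always(self, small_run):
        for seg in small_run.segmentations.values():
            assert not np.any(seg.lamellae_mask & ~seg.media_mask)


class TestSliceInvariants:
    def test_all_set_invariants_every_slice(self, small_run):
        for seg in small_run.segmentations.values():
            seg.check_invariants()

    def test_media_plus_adventitia_is_wall_exactly(self, small_run):
        for seg in small_run.segmentations.values():
            assert (
                seg.media_mask.sum() + seg.adventitia_mask.sum() == seg.wall_mask.sum()
            )


@pytest.fixture(scope="module")
def elliptical_slice():
    spec = PhantomSpec(
        n_slices=9, slice_shape=(448, 448), lumen_radius_px=70.0, wall_thickness_px=28.0,
        lamella_thickness_px=2.0,
        dilation=DilationSpec(start=0, end=8, max_scale=1.1, axis_ratio=1.45),
    )
    grid, truth = generate_phantom(spec)
    return grid.data[4], truth


class TestDilatedFallback:
    def test_elliptical_lumen_area_within_3pct(self, elliptical_slice):
        img, truth = elliptical_slice
        wall, lumen = sg.segment_dilated_fallback(img)
        true_area = math.pi * (
            truth.per_slice.lumen_semi_axis_row_px[4] * truth.per_slice.lumen_semi_axis_col_px[4]
        )
        assert lumen.sum() == pytest.approx(true_area, rel=0.03)

    def test_circular_slice_consistent_with_standard_path(self, small_phantom):
        grid, _ = small_phantom
        wall_std = sg.segment_wall(grid.data[0])
        lumen_std, _ = sg.segment_lumen(wall_std)
        _, lumen_fb = sg.segment_dilated_fallback(grid.data[0])
        assert dice(lumen_std, lumen_fb) >= 0.98

    def test_open_wall_gap_closed_by_watershed(self):
        spec = PhantomSpec(
            n_slices=5, slice_shape=(384, 384), lumen_radius_px=70.0, wall_thickness_px=28.0,
            lamella_thickness_px=2.0,
            breaks=(BreakSpec(0, 4, 40, 75, None, through_wall=True),),
        )
        grid, _ = generate_phantom(spec)
        wall = sg.segment_wall(grid.data[2])
        with pytest.raises(sg.OpenWallError):
            sg.segment_lumen(wall)
        _, lumen = sg.segment_dilated_fallback(grid.data[2])
        assert lumen.sum() == pytest.approx(math.pi * 70.0**2, rel=0.03)

    def test_gap_over_90_degrees_fails(self):
        spec = PhantomSpec(
            n_slices=3, slice_shape=(384, 384), lumen_radius_px=70.0, wall_thickness_px=28.0,
            lamella_thickness_px=2.0,
            breaks=(BreakSpec(0, 2, 30, 140, None, through_wall=True),),
        )
        grid, _ = generate_phantom(spec)
        with pytest.raises(sg.FallbackFailedError):
            sg.segment_dilated_fallback(grid.data[1])


class TestLimitOverride:
    def test_identical_override_is_fixed_point(self, small_run):
        segs = copy.deepcopy([small_run.segmentations[z] for z in sorted(small_run.segmentations)])
        before = [s.media_radius.copy() for s in segs]
        sg.apply_limit_override(segs, 6, segs[6].media_adventitia_contour.copy())
        for s, b in zip(segs, before):
            assert np.allclose(s.media_radius, b, atol=1e-9)

    def test_outward_push_decays_monotonically(self, small_run):
        segs = copy.deepcopy([small_run.segmentations[z] for z in sorted(small_run.segmentations)])
        before = [s.media_radius.copy() for s in segs]
        c = segs[6].lumen_centroid
        pts = segs[6].media_adventitia_contour
        r = np.hypot(*(pts - c).T)
        pushed = c[None, :] + (pts - c) * ((r + 5.0) / r)[:, None]
        sg.apply_limit_override(segs, 6, pushed)
        shifts = np.array([np.mean(s.media_radius - b) for s, b in zip(segs, before)])
        assert shifts[6] == pytest.approx(5.0, abs=0.2)
        assert np.all(np.diff(shifts[6:]) <= 1e-9)
        assert np.all(np.diff(shifts[: 6 + 1]) >= -1e-9)
        assert segs[6].provenance == "override"

    def test_two_far_overrides_converge_locally(self, small_run):
        segs = copy.deepcopy([small_run.segmentations[z] for z in sorted(small_run.segmentations)])
        before = [s.media_radius.copy() for s in segs]
        for idx, delta in ((2, 4.0), (10, -3.0)):
            c = segs[idx].lumen_centroid
            pts = segs[idx].media_adventitia_contour
            r = np.hypot(*(pts - c).T)
            pushed = c[None, :] + (pts - c) * ((r + delta) / r)[:, None]
            sg.apply_limit_override(segs, idx, pushed, decay_slices=2.0)
        shifts = np.array([np.mean(s.media_radius - b) for s, b in zip(segs, before)])
        # each local neighbourhood converges to its own anchor
        assert shifts[2] == pytest.approx(4.0, abs=0.3)
        assert shifts[10] == pytest.approx(-3.0, abs=0.3)

    def test_override_not_enclosing_lumen_rejected(self, small_run):
        segs = copy.deepcopy([small_run.segmentations[z] for z in sorted(small_run.segmentations)])
        c = segs[6].lumen_centroid
        tiny = c[None, :] + (segs[6].lumen_contour - c[None, :]) * 0.5
        with pytest.raises(ValueError, match="enclose"):
            sg.apply_limit_override(segs, 6, tiny)
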