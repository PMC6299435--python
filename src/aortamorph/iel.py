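"""Internal elastic lamina (IEL) surface extraction and break analysis.

The IEL borders the lumen (the intima gives no phase contrast), so the
lumen–wall limit marks its location.  Per slice, that 1-px border is
dilated by a disk (7 px by default captures the whole IEL) and
intersected with the wall, giving a thin 3D shell.  Projecting the
maximal intensity through the shell along each unwrapping ray yields an
en-face image of the luminal surface (axial position × circumferential
angle), on which breaks appear as dark discontinuities and are
quantified as a percentage of the surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .geometry import TWO_PI, unwrap_polar

__all__ = [
    "IELSurfaceImage",
    "BreakRegion",
    "extract_iel",
    "enface_projection",
    "quantify_breaks",
]


def extract_iel(
    lumen_masks: np.ndarray | list[np.ndarray],
    wall_masks: np.ndarray | list[np.ndarray],
    iel_dilation_px: int = 7,
) -> np.ndarray:
    """IEL shell: per slice, the 1-px lumen–wall border dilated by a disk
    of radius ``iel_dilation_px``, intersected with the wall."""
    n = len(lumen_masks)
    if n == 0:
        raise ValueError("no slices")
    missing = [i for i in range(n) if not np.any(lumen_masks[i])]
    if missing:
        raise ValueError(f"missing lumen contour on slices {missing}")
    shell = np.zeros((n,) + np.asarray(lumen_masks[0]).shape, dtype=bool)
    for i in range(n):
        lumen = np.asarray(lumen_masks[i], dtype=bool)
        border = morphology.dilation(lumen, morphology.disk(1)) & ~lumen
        if iel_dilation_px > 0:
            # exact Euclidean dilation by a disk of the configured radius
            border = ndimage.distance_transform_edt(~border) <= iel_dilation_px
        shell[i] = border & np.asarray(wall_masks[i], dtype=bool)
    return shell


@dataclass
class IELSurfaceImage:
    """En-face maximal projection of the IEL shell.

    ``data[i, k]`` is the maximal intensity on slice i along the ray at
    angle sample k; ``arc_pitch_um[i]`` is the circumferential extent of
    one angular sample on that slice (2 pi x mean lumen radius / K x
    voxel), so pixel areas follow the local lumen radius.
    """

    data: np.ndarray  # (n_slices, K)
    valid: np.ndarray  # (n_slices, K) bool
    arc_pitch_um: np.ndarray  # (n_slices,)
    axial_pitch_um: float
    angles: np.ndarray  # (K,)

    @property
    def pixel_area_um2(self) -> np.ndarray:
        """Per-row pixel area (n_slices,) in µm²."""
        return self.arc_pitch_um * self.axial_pitch_um

    def total_valid_area_um2(self) -> float:
        return float((self.valid.sum(axis=1) * self.pixel_area_um2).sum())


def enface_projection(
    intensity_stack: np.ndarray,
    shell: np.ndarray,
    lumen_contours: list[np.ndarray],
    voxel_size_um: float,
    angular_samples: int = 720,
    depth_px: int | None = None,
    contour_smoothing: float = 0.5,
) -> IELSurfaceImage:
    """Maximal intensity through the IEL shell along each unwrapping ray.

    The same local-centre geometry as the virtual opening is used: rays
    start at the lumen–wall limit and follow the local outward normal.
    Columns whose ray never meets the shell are marked invalid, not
    interpolated.
    """
    n = len(intensity_stack)
    if len(shell) != n or len(lumen_contours) != n:
        raise ValueError("stack, shell and contours must cover the same slices")
    if depth_px is None:
        depth_px = 16
    data = np.zeros((n, angular_samples), dtype=np.float32)
    valid = np.zeros((n, angular_samples), dtype=bool)
    arc = np.zeros(n)
    for i in range(n):
        uw_int = unwrap_polar(
            intensity_stack[i],
            lumen_contours[i],
            angular_samples,
            depth_px=depth_px,
            contour_smoothing=contour_smoothing,
        )
        uw_shell = unwrap_polar(
            shell[i].astype(np.float32),
            lumen_contours[i],
            angular_samples,
            depth_px=depth_px,
            contour_smoothing=contour_smoothing,
        )
        in_shell = uw_shell.data >= 0.5
        has = in_shell.any(axis=1)
        vals = np.where(in_shell, uw_int.data, -np.inf).max(axis=1)
        data[i, has] = vals[has]
        valid[i] = has
        mean_radius = float(
            np.mean(np.hypot(*(uw_int.origins - uw_int.center[None, :]).T))
        )
        arc[i] = TWO_PI * mean_radius / angular_samples * voxel_size_um
    return IELSurfaceImage(
        data=data,
        valid=valid,
        arc_pitch_um=arc,
        axial_pitch_um=voxel_size_um,
        angles=np.arange(angular_samples) * TWO_PI / angular_samples,
    )


@dataclass
class BreakRegion:
    """One connected dark component on the en-face surface."""

    region_id: int
    area_um2: float
    n_pixels: int
    slice_range: tuple[int, int]
    angle_range_deg: tuple[float, float]
    centroid: tuple[float, float]  # (slice, angle sample)


def _refine_half_contrast(
    surface: IELSurfaceImage, dark: np.ndarray, margin: int = 8
) -> np.ndarray:
    """Grow each detected dark component out to its half-contrast boundary.

    The seed threshold is deliberately conservative (intact surfaces must
    yield nothing), so it sizes breaks short of their true edge.  For
    each seed component the local bright reference (median of nearby
    valid pixels outside the component) and dark core level (median of
    the component) define a midpoint threshold at which the component is
    re-grown — the usual half-maximum sizing convention.
    """
    valid = surface.valid
    labels, n_lab = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    refined = np.zeros_like(dark)
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        rr, cc = np.nonzero(comp)
        r0 = max(0, rr.min() - margin)
        r1 = min(dark.shape[0], rr.max() + margin + 1)
        c0 = max(0, cc.min() - margin)
        c1 = min(dark.shape[1], cc.max() + margin + 1)
        box = (slice(r0, r1), slice(c0, c1))
        comp_box = comp[box]
        data_box = surface.data[box]
        valid_box = valid[box]
        near = ndimage.binary_dilation(comp_box, iterations=3)
        ref_px = data_box[valid_box & ~near]
        if ref_px.size == 0:
            refined[box] |= comp_box
            continue
        bright = float(np.median(ref_px))
        core = float(np.median(data_box[comp_box]))
        thr_local = 0.5 * (bright + core)
        cand = valid_box & (data_box < thr_local)
        lab2, _ = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
        keep = np.unique(lab2[comp_box])
        keep = keep[keep > 0]
        refined[box] |= np.isin(lab2, keep)
    return refined


def quantify_breaks(
    surface: IELSurfaceImage,
    threshold: float | None = None,
    relative_threshold: float = 0.75,
    min_break_area_um2: float = 50.0,
    manual_mask: np.ndarray | None = None,
) -> tuple[list[BreakRegion], float]:
    """Detect and measure IEL breaks on the en-face surface.

    Breaks are 8-connected components of sub-threshold pixels; the seed
    threshold is either fixed (``threshold``) or ``relative_threshold``
    x the median valid intensity, and each seed component is then sized
    at its local half-contrast boundary.  A ``manual_mask`` (same shape)
    bypasses detection entirely, mirroring manual contour delimitation.
    Returns ``(regions, pct)`` with pct = 100 x total break area / valid
    surface area; areas use the per-slice arc pitch.
    """
    valid = surface.valid
    if not valid.any():
        raise ValueError("surface has no valid pixels")
    if manual_mask is not None:
        dark = np.asarray(manual_mask, dtype=bool) & valid
    else:
        if threshold is None:
            threshold = relative_threshold * float(np.median(surface.data[valid]))
        dark = valid & (surface.data < threshold)
        dark = _refine_half_contrast(surface, dark)
        if dark.sum() > 0.5 * valid.sum():
            warnings.warn(
                "more than half of the IEL surface is below the break "
                "threshold; the surface is dominated by breaks",
                stacklevel=2,
            )

    labels, n_lab = ndimage.label(dark, structure=np.ones((3, 3), dtype=int))
    pixel_area = surface.pixel_area_um2  # per-row
    regions: list[BreakRegion] = []
    total_area = 0.0
    deg_per_sample = 360.0 / surface.data.shape[1]
    for lab in range(1, n_lab + 1):
        rr, cc = np.nonzero(labels == lab)
        area = float(pixel_area[rr].sum())
        if area < min_break_area_um2:
            continue
        regions.append(
            BreakRegion(
                region_id=len(regions),
                area_um2=area,
                n_pixels=len(rr),
                slice_range=(int(rr.min()), int(rr.max())),
                angle_range_deg=(cc.min() * deg_per_sample, cc.max() * deg_per_sample),
                centroid=(float(rr.mean()), float(cc.mean())),
            )
        )
        total_area += area
    pct = 100.0 * total_area / surface.total_valid_area_um2()
    return regions, pct


def breaks_to_frame(regions: list[BreakRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.region_id,
                "area_um2": r.area_um2,
                "n_pixels": r.n_pixels,
                "slice_start": r.slice_range[0],
                "slice_end": r.slice_range[1],
                "angle_start_deg": r.angle_range_deg[0],
                "angle_end_deg": r.angle_range_deg[1],
            }
            for r in regions
        ],
        columns=[
            "id",
            "area_um2",
            "n_pixels",
            "slice_start",
            "slice_end",
            "angle_start_deg",
            "angle_end_deg",
        ],
    )
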