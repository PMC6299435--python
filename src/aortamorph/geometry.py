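"""Vessel geometry: centreline, orthogonal reslicing, polar unwrapping.

The "virtual opening" of the vessel is a local Cartesian-to-polar
transformation: each point of the lumen–wall limit acts as a local
centre, and the wall is resampled along the outward normal of the
(smoothed) lumen contour, turning the annular wall into a straight band
whose depth axis starts at the luminal boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, ndimage
from skimage import measure

__all__ = [
    "Centerline",
    "UnwrappedSlice",
    "extract_contour",
    "contour_radius",
    "smooth_radius_periodic",
    "compute_centerline",
    "reslice_orthogonal",
    "unwrap_polar",
    "rewrap_mask",
    "select_central_window",
]

TWO_PI = 2.0 * math.pi


# --------------------------------------------------------------------------
# contours


def extract_contour(mask: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Subpixel boundary of a binary mask as an ordered (N, 2) array of
    (row, col) points, counter-clockwise (in image axes) starting at
    angle 0 from the mask centroid."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    contour = max(contours, key=len)
    if center is None:
        rr, cc = np.nonzero(mask)
        center = np.array([rr.mean(), cc.mean()])
    theta = np.arctan2(contour[:, 0] - center[0], contour[:, 1] - center[1])
    theta = np.mod(theta, TWO_PI)
    # enforce increasing angle, starting nearest 0
    order = np.argsort(theta, kind="stable")
    return contour[order]


def contour_radius(contour: np.ndarray, center: np.ndarray, n_angles: int) -> np.ndarray:
    """Resample the radius function r(theta) of a closed contour on a
    uniform angular grid of ``n_angles`` samples in [0, 2 pi)."""
    d = contour - center[None, :]
    theta = np.mod(np.arctan2(d[:, 0], d[:, 1]), TWO_PI)
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(theta, kind="stable")
    theta, r = theta[order], r[order]
    theta_ext = np.concatenate([theta - TWO_PI, theta, theta + TWO_PI])
    r_ext = np.concatenate([r, r, r])
    grid = np.arange(n_angles) * TWO_PI / n_angles
    return np.interp(grid, theta_ext, r_ext)


def smooth_radius_periodic(radius: np.ndarray, smoothing: float = 0.5) -> np.ndarray:
    """Smooth a uniformly sampled periodic radius profile with a periodic
    cubic smoothing spline.  ``smoothing`` is the per-sample residual
    budget in px² (scipy's ``s`` = smoothing * n)."""
    n = len(radius)
    theta = np.arange(n + 1) * TWO_PI / n
    r = np.concatenate([radius, radius[:1]])
    tck = interpolate.splrep(theta, r, per=1, s=smoothing * n)
    return interpolate.splev(theta[:-1], tck)


def radius_to_points(
    center: np.ndarray, radius: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cartesian points and outward normals of a sampled radius profile.

    Normals are the true curve normals of gamma(theta) = c + r(theta) u(theta),
    oriented outward.  Returns (points (K, 2), normals (K, 2)) in (row, col).
    """
    k = len(radius)
    theta = np.arange(k) * TWO_PI / k
    u = np.column_stack([np.sin(theta), np.cos(theta)])  # radial unit (row, col)
    pts = center[None, :] + radius[:, None] * u
    # tangent by periodic central differences
    tang = np.empty_like(pts)
    tang[1:-1] = pts[2:] - pts[:-2]
    tang[0] = pts[1] - pts[-1]
    tang[-1] = pts[0] - pts[-2]
    # rotate tangent by -90 deg in (row, col) plane; orient outward
    normals = np.column_stack([tang[:, 1], -tang[:, 0]])
    flip = np.einsum("ij,ij->i", normals, u) < 0
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1)
    normals /= norms[:, None]
    return pts, normals


# --------------------------------------------------------------------------
# centreline


@dataclass
class Centerline:
    """Smooth 3D curve through per-slice lumen centroids, parameterised by
    slice index z."""

    z: np.ndarray  # (S,)
    centroids: np.ndarray  # (S, 2) of (row, col)
    _tck_row: tuple
    _tck_col: tuple

    def point(self, z: float | np.ndarray) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        row = interpolate.splev(z, self._tck_row)
        col = interpolate.splev(z, self._tck_col)
        return np.column_stack([z, row, col]).squeeze()

    def tangent(self, z: float | np.ndarray) -> np.ndarray:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        drow = interpolate.splev(z, self._tck_row, der=1)
        dcol = interpolate.splev(z, self._tck_col, der=1)
        t = np.column_stack([np.ones_like(z), drow, dcol])
        n = np.linalg.norm(t, axis=1, keepdims=True)
        if np.any(n == 0):
            raise ValueError("degenerate centreline tangent")
        return (t / n).squeeze()

    def arclength_grid(self, step: float = 1.0) -> np.ndarray:
        """z positions spaced ``step`` px apart in arc length."""
        zf = np.linspace(self.z[0], self.z[-1], max(len(self.z) * 8, 64))
        pts = self.point(zf).reshape(-1, 3)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        stations = np.arange(0.0, s[-1] + 1e-9, step)
        return np.interp(stations, s, zf)


def compute_centerline(
    lumen_masks: np.ndarray | list[np.ndarray],
    smoothing: float = 0.0,
    z_values: np.ndarray | None = None,
) -> Centerline:
    """Cubic smoothing spline through the lumen centroids of all slices.

    ``smoothing`` is the per-slice residual budget in px² (scipy's ``s``
    = smoothing * n); 0 interpolates exactly.
    """
    centroids = []
    for m in lumen_masks:
        rr, cc = np.nonzero(m)
        if len(rr) == 0:
            raise ValueError("empty lumen mask")
        centroids.append((rr.mean(), cc.mean()))
    centroids = np.asarray(centroids)
    n = len(centroids)
    if n < 4:
        raise ValueError(f"need >= 4 slices with valid lumina, got {n}")
    z = np.arange(n, dtype=float) if z_values is None else np.asarray(z_values, float)
    s = smoothing * n
    tck_row = interpolate.splrep(z, centroids[:, 0], s=s)
    tck_col = interpolate.splrep(z, centroids[:, 1], s=s)
    return Centerline(z=z, centroids=centroids, _tck_row=tck_row, _tck_col=tck_col)


# --------------------------------------------------------------------------
# orthogonal reslicing


def reslice_orthogonal(grid, centerline: Centerline, order: int = 1):
    """Resample the stack on planes orthogonal to the local centreline
    tangent, centred on the centreline, spaced one voxel apart in arc
    length.  In-plane frames are parallel-transported from the first
    plane, so no axial twist is introduced.
    """
    from .io import VoxelGrid3D

    data = grid.data
    s_dim, h, w = data.shape
    z_stations = centerline.arclength_grid(step=1.0)
    tangents = np.atleast_2d(centerline.tangent(z_stations))
    points = np.atleast_2d(centerline.point(z_stations))

    # initial in-plane basis: project image axes onto the first plane
    t0 = tangents[0]
    e_row = np.array([0.0, 1.0, 0.0]) - np.dot([0.0, 1.0, 0.0], t0) * t0
    e_row /= np.linalg.norm(e_row)
    e_col = np.cross(t0, e_row)

    rows = np.arange(h, dtype=np.float64) - (h - 1) / 2.0
    cols = np.arange(w, dtype=np.float64) - (w - 1) / 2.0
    rr, cc = np.meshgrid(rows, cols, indexing="ij")

    out = np.empty((len(z_stations), h, w), dtype=np.float32)
    for i, (p, t) in enumerate(zip(points, tangents)):
        if i > 0:
            # parallel transport of the frame onto the new plane
            e_row = e_row - np.dot(e_row, t) * t
            e_row /= np.linalg.norm(e_row)
            e_col = np.cross(t, e_row)
        coords = (
            p[:, None, None]
            + e_row[:, None, None] * rr[None]
            + e_col[:, None, None] * cc[None]
        )
        out[i] = ndimage.map_coordinates(
            data, coords.reshape(3, -1), order=order, mode="nearest"
        ).reshape(h, w)
    return VoxelGrid3D(
        data=out, voxel_size_um=grid.voxel_size_um, source_dtype=grid.source_dtype
    )


# --------------------------------------------------------------------------
# polar unwrapping ("virtual opening")


@dataclass
class UnwrappedSlice:
    """One slice of the virtually opened vessel.

    ``data[k, j]`` is the intensity at angle sample k and radial depth
    j * radial_step_px outward from the lumen–wall limit (depth 0 = the
    limit itself).
    """

    data: np.ndarray  # (K, D)
    angles: np.ndarray  # (K,) radians
    radial_step_px: float
    origins: np.ndarray  # (K, 2) subpixel (row, col) of depth-0 points
    normals: np.ndarray  # (K, 2) outward unit normals
    center: np.ndarray  # (2,) lumen centroid used for the angular grid

    @property
    def angular_step(self) -> float:
        return TWO_PI / len(self.angles)


def unwrap_polar(
    image: np.ndarray,
    lumen_contour: np.ndarray,
    angular_samples: int = 720,
    depth_px: int = 64,
    radial_step_px: float = 1.0,
    center: np.ndarray | None = None,
    contour_smoothing: float = 0.5,
    order: int = 1,
) -> UnwrappedSlice:
    """Virtually open one slice about its lumen contour.

    Rays start at the smoothed lumen–wall limit and follow the local
    outward normal; the image is sampled bilinearly (``order=1``) at
    ``radial_step_px`` increments.
    """
    if center is None:
        center = lumen_contour.mean(axis=0)
    center = np.asarray(center, dtype=float)
    radius = contour_radius(lumen_contour, center, angular_samples)
    radius = smooth_radius_periodic(radius, contour_smoothing)
    if np.any(radius <= 0):
        raise ValueError("self-intersecting or degenerate contour")
    origins, normals = radius_to_points(center, radius)
    depths = np.arange(depth_px) * radial_step_px
    coords = origins[:, None, :] + depths[None, :, None] * normals[:, None, :]
    sampled = ndimage.map_coordinates(
        np.asarray(image, dtype=np.float64),
        [coords[..., 0].ravel(), coords[..., 1].ravel()],
        order=order,
        mode="constant",
        cval=0.0,
    ).reshape(angular_samples, depth_px)
    angles = np.arange(angular_samples) * TWO_PI / angular_samples
    return UnwrappedSlice(
        data=sampled.astype(np.float32),
        angles=angles,
        radial_step_px=radial_step_px,
        origins=origins,
        normals=normals,
        center=center,
    )


def rewrap_mask(
    unwrapped: UnwrappedSlice, band: np.ndarray, shape: tuple[int, int], supersample: int = 3
) -> np.ndarray:
    """Map an unwrapped binary band back into Cartesian pixel space.

    Forward-maps each active (angle, depth) cell (supersampled to close
    gaps where rays diverge) and rasterises to the nearest pixel.
    """
    k, d = band.shape
    ss = supersample
    # supersample angularly by interpolating origins/normals periodically
    fine = (np.arange(k * ss) + 0.0) / ss
    base = np.arange(k + 1, dtype=float)
    origins = np.vstack([unwrapped.origins, unwrapped.origins[:1]])
    normals = np.vstack([unwrapped.normals, unwrapped.normals[:1]])
    o_fine = np.column_stack(
        [np.interp(fine, base, origins[:, 0]), np.interp(fine, base, origins[:, 1])]
    )
    n_fine = np.column_stack(
        [np.interp(fine, base, normals[:, 0]), np.interp(fine, base, normals[:, 1])]
    )
    n_fine /= np.linalg.norm(n_fine, axis=1, keepdims=True)

    depths = (np.arange(d * ss) + 0.5) / ss - 0.5
    band_fine = band[np.minimum((fine + 0.5).astype(int) % k, k - 1)]
    band_fine = band_fine[:, np.clip(np.rint(depths).astype(int), 0, d - 1)]

    ai, di = np.nonzero(band_fine)
    pts = o_fine[ai] + depths[di][:, None] * n_fine[ai] * unwrapped.radial_step_px
    rr = np.rint(pts[:, 0]).astype(int)
    cc = np.rint(pts[:, 1]).astype(int)
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    out = np.zeros(shape, dtype=bool)
    out[rr[keep], cc[keep]] = True
    return out


# --------------------------------------------------------------------------
# central window


def select_central_window(n_total: int, n: int) -> range:
    """Contiguous range of ``n`` slices centred on the stack midpoint
    (floor division for odd remainders)."""
    if n_total < n:
        raise ValueError(f"stack has {n_total} slices, {n} required")
    start = (n_total - n) // 2
    return range(start, start + n)
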