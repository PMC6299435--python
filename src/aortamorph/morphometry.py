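"""Per-slice and per-stack histological parameters.

Implements the transverse measurements of the wall: lumen diameter via
a direct least-squares ellipse fit (mean of major and minor axes, the
echocardiography convention), media thickness sampled along contour
normals with a Gaussian fitted to its histogram, cross-sectional areas
by pixel counting, and the lamellar fraction of the media.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.measure import EllipseModel

from .geometry import radius_to_points

__all__ = [
    "ThicknessDistribution",
    "MorphometryRecord",
    "StackSummary",
    "euclidean_distance_transform",
    "media_thickness",
    "cross_sectional_area",
    "lamellae_fraction",
    "lumen_diameter",
    "summarize_stack",
    "records_to_frame",
]


def euclidean_distance_transform(mask: np.ndarray) -> np.ndarray:
    """Exact per-pixel Euclidean distance (px) to the nearest background
    pixel; zero everywhere for an all-background mask."""
    return ndimage.distance_transform_edt(np.asarray(mask, dtype=bool))


@dataclass
class ThicknessDistribution:
    """Per-angle media thickness samples with their histogram Gaussian fit."""

    samples_um: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    mean_um: float  # Gaussian-fit mean (primary)
    sd_um: float  # Gaussian-fit sd
    fit_residual: float
    sample_mean_um: float
    sample_sd_um: float
    n_samples: int
    n_dropped: int = 0
    high_drop_warning: bool = False


def _gaussian(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _fit_gaussian(samples: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Freedman–Diaconis histogram + least-squares Gaussian fit.

    Returns (edges, counts, mean, sd, residual).  Degenerate samples
    (essentially a single value) short-circuit to (value, 0).
    """
    mu0 = float(np.mean(samples))
    sd0 = float(np.std(samples))
    counts, edges = np.histogram(samples, bins="fd")
    if sd0 < 1e-9 or len(edges) < 4:
        return edges, counts, mu0, sd0, 0.0
    centers = 0.5 * (edges[:-1] + edges[1:])
    try:
        popt, _ = optimize.curve_fit(
            _gaussian,
            centers,
            counts,
            p0=[counts.max(), mu0, max(sd0, 1e-6)],
            maxfev=5000,
        )
        amp, mu, sigma = popt
        sigma = abs(float(sigma))
        mu = float(mu)
        resid = float(np.sqrt(np.mean((_gaussian(centers, *popt) - counts) ** 2)))
        if not (samples.min() - 3 * sd0 <= mu <= samples.max() + 3 * sd0):
            raise RuntimeError("fit diverged")
    except RuntimeError:
        mu, sigma, resid = mu0, sd0, float("nan")
    return edges, counts, mu, sigma, resid


def media_thickness(
    media_mask: np.ndarray,
    lumen_center: np.ndarray,
    lumen_radius: np.ndarray,
    voxel_size_um: float,
    step_px: float = 0.25,
    max_depth_px: float | None = None,
) -> ThicknessDistribution:
    """Media thickness at each angular sample, along the local normal of
    the lumen–wall limit, from that limit to the media–adventitia limit.

    ``lumen_radius`` is the smoothed r(theta) profile of the lumen–wall
    limit on the uniform angular grid; the media mask is sampled
    bilinearly along each normal ray until it is exited.  Rays that fail
    to enter the media are dropped and counted.
    """
    k = len(lumen_radius)
    origins, normals = radius_to_points(np.asarray(lumen_center, float), lumen_radius)
    if max_depth_px is None:
        max_depth_px = 4.0 + 2.0 * float(
            euclidean_distance_transform(media_mask).max(initial=0.0)
        )
    depths = np.arange(step_px, max_depth_px, step_px)
    coords = origins[:, None, :] + depths[None, :, None] * normals[:, None, :]
    inside = (
        ndimage.map_coordinates(
            media_mask.astype(np.float32),
            [coords[..., 0].ravel(), coords[..., 1].ravel()],
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(k, len(depths))
        >= 0.5
    )
    samples = []
    dropped = 0
    for ray in inside:
        hits = np.nonzero(ray)[0]
        if len(hits) == 0:
            dropped += 1
            continue
        # thickness = extent of the first contiguous in-media run
        start = hits[0]
        off = np.nonzero(~ray[start:])[0]
        end = start + (off[0] if len(off) else len(ray) - start)
        samples.append((depths[end - 1] + step_px / 2.0))
    if not samples:
        raise ValueError("no thickness samples: media mask unreachable from contour")
    samples_um = np.asarray(samples) * voxel_size_um
    edges, counts, mu, sigma, resid = _fit_gaussian(samples_um)
    return ThicknessDistribution(
        samples_um=samples_um,
        bin_edges=edges,
        counts=counts,
        mean_um=mu,
        sd_um=sigma,
        fit_residual=resid,
        sample_mean_um=float(np.mean(samples_um)),
        sample_sd_um=float(np.std(samples_um)),
        n_samples=len(samples_um),
        n_dropped=dropped,
        high_drop_warning=dropped > 0.1 * k,
    )


def cross_sectional_area(mask: np.ndarray, voxel_size_um: float) -> float:
    """Pixel count x voxel area (µm²)."""
    return float(np.count_nonzero(mask)) * voxel_size_um**2


def lamellae_fraction(
    lamellae_mask: np.ndarray, media_mask: np.ndarray, voxel_size_um: float = 1.0
) -> tuple[float, float, float]:
    """Percentage of the medial space occupied by lamellae, plus the
    lamellar and interlamellar areas (µm²).  The partition is exact:
    lamellar + interlamellar = media area in integer pixel counts."""
    lam = np.asarray(lamellae_mask, dtype=bool)
    med = np.asarray(media_mask, dtype=bool)
    if np.any(lam & ~med):
        raise ValueError("lamellae mask is not a subset of the media mask")
    n_med = int(np.count_nonzero(med))
    if n_med == 0:
        raise ValueError("empty media mask")
    n_lam = int(np.count_nonzero(lam))
    v2 = voxel_size_um**2
    return 100.0 * n_lam / n_med, n_lam * v2, (n_med - n_lam) * v2


def lumen_diameter(
    lumen_contour: np.ndarray, voxel_size_um: float
) -> tuple[float, dict]:
    """Diameter from a direct least-squares ellipse fit of the internal
    circumference: (major + minor axis) / 2, in µm."""
    pts = np.asarray(lumen_contour, dtype=float)
    if len(pts) < 6:
        raise ValueError("need >= 6 contour points for an ellipse fit")
    model = EllipseModel.from_estimate(pts[:, ::-1])  # EllipseModel expects (x, y)
    if not model:
        raise ValueError("degenerate ellipse fit (collinear points?)")
    xc, yc = model.center
    a, b = model.axis_lengths
    theta = model.theta
    if not np.isfinite([xc, yc, a, b, theta]).all() or a <= 0 or b <= 0:
        raise ValueError("degenerate ellipse fit")
    major, minor = max(a, b), min(a, b)
    diameter = (major + minor) * voxel_size_um  # mean of full axes = a + b
    params = {
        "center_row": yc,
        "center_col": xc,
        "semi_major_px": major,
        "semi_minor_px": minor,
        "orientation_rad": theta,
    }
    return diameter, params


@dataclass
class MorphometryRecord:
    """Per-slice quantities; thickness is absent on fallback slices."""

    slice_index: int
    lumen_diameter_um: float
    media_area_um2: float | None
    lamellae_area_um2: float | None
    interlamellar_area_um2: float | None
    lamellae_pct: float | None
    thickness: ThicknessDistribution | None
    provenance: str = "auto"

    @property
    def media_thickness_um(self) -> float:
        return self.thickness.mean_um if self.thickness is not None else float("nan")


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "slice": r.slice_index,
                "lumen_diameter_um": r.lumen_diameter_um,
                "media_thickness_um": r.media_thickness_um,
                "media_thickness_sd_um": (
                    r.thickness.sd_um if r.thickness is not None else float("nan")
                ),
                "media_area_um2": np.nan if r.media_area_um2 is None else r.media_area_um2,
                "lamellae_area_um2": (
                    np.nan if r.lamellae_area_um2 is None else r.lamellae_area_um2
                ),
                "interlamellar_area_um2": (
                    np.nan if r.interlamellar_area_um2 is None else r.interlamellar_area_um2
                ),
                "lamellae_pct": np.nan if r.lamellae_pct is None else r.lamellae_pct,
                "provenance": r.provenance,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StackSummary:
    """Means ± SD over the analysed window plus the pooled thickness
    samples (for frequency-distribution plots)."""

    n_slices: int
    means: pd.Series
    sds: pd.Series
    pooled_thickness_um: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.means, "sd": self.sds})


def summarize_stack(records: list[MorphometryRecord]) -> StackSummary:
    if not records:
        raise ValueError("no records to summarise")
    frame = records_to_frame(records)
    cols = [
        "lumen_diameter_um",
        "media_thickness_um",
        "media_area_um2",
        "lamellae_area_um2",
        "interlamellar_area_um2",
        "lamellae_pct",
    ]
    means = frame[cols].mean()
    sds = frame[cols].std(ddof=0).fillna(0.0)
    pooled = [
        r.thickness.mean_um for r in records if r.thickness is not None
    ]
    return StackSummary(
        n_slices=len(records),
        means=means,
        sds=sds,
        pooled_thickness_um=np.asarray(pooled, dtype=float),
    )
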