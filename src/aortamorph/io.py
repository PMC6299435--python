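"""Stack I/O, physical metadata and pipeline configuration.

All images live in memory as float32 ``(slice, row, col)`` arrays with a
single isotropic voxel size in µm; the source bit depth is recorded so
writes can round-trip losslessly.  Coordinates are 0-based; contours are
ordered lists of subpixel (row, col) points; every physical output is in
µm / µm² via ``voxel_size_um``.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelGrid3D",
    "PipelineConfig",
    "read_stack",
    "write_stack",
    "load_config",
    "sha256_of_file",
]


@dataclass
class VoxelGrid3D:
    """A 3D greyscale stack with isotropic physical voxel size."""

    data: np.ndarray  # (slice, row, col), float32
    voxel_size_um: float
    source_dtype: str = "float32"
    axis_order: str = "zyx"

    def __post_init__(self):
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("data must be a 3D array with all dimensions >= 1")
        self.data = np.asarray(self.data, dtype=np.float32)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


def _natural_key(name: str):
    return [int(tok) if tok.isdigit() else tok.lower() for tok in re.split(r"(\d+)", name)]


def read_stack(path: str | Path, voxel_size_um: float) -> VoxelGrid3D:
    """Read a multi-page TIFF, or a directory of single-page TIFFs ordered
    by natural sort of their filenames (img_2 before img_10)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=lambda p: _natural_key(p.name),
        )
        if not files:
            raise ValueError(f"no TIFF files found in directory {path}")
        pages = [tifffile.imread(f) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) > 1:
            for i, p in enumerate(pages):
                if p.shape != pages[0].shape:
                    raise ValueError(
                        f"mixed slice shapes: {files[i].name} has {p.shape}, "
                        f"expected {pages[0].shape}"
                    )
        arr = np.stack(pages)
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] == 0:
        raise ValueError(f"expected a stack of 2D slices, got shape {arr.shape}")
    src = str(arr.dtype)
    return VoxelGrid3D(
        data=arr.astype(np.float32), voxel_size_um=voxel_size_um, source_dtype=src
    )


def write_stack(grid: VoxelGrid3D | np.ndarray, path: str | Path) -> Path:
    """Write a stack as multi-page TIFF.

    Boolean / mask stacks are written 8-bit {0, 255}.  A ``VoxelGrid3D``
    is written in its recorded source dtype (integer sources are rounded
    and clipped; float sources written as float32), so
    ``read_stack(write_stack(x))`` is lossless for supported dtypes.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(grid, VoxelGrid3D):
        data = grid.data
        dt = np.dtype(grid.source_dtype)
        if np.issubdtype(dt, np.integer):
            info = np.iinfo(dt)
            out = np.clip(np.rint(data), info.min, info.max).astype(dt)
        else:
            out = data.astype(np.float32)
    else:
        arr = np.asarray(grid)
        if arr.dtype == bool:
            out = (arr.astype(np.uint8)) * 255
        elif arr.dtype == np.uint8 and arr.max(initial=0) <= 1:
            out = arr * 255
        else:
            out = arr
    if out.ndim == 2:
        out = out[None]
    tifffile.imwrite(path, out, photometric="minisblack")
    return path


def sha256_of_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# --------------------------------------------------------------------------
# pipeline configuration


@dataclass
class PipelineConfig:
    """Tunable constants of the measurement pipeline.

    Defaults encode the published analysis protocol: a central window of
    200 slices, the media–adventitia limit obtained by dilating the inner
    wall half with a structuring element of 0.35 × the minimum wall
    thickness, a 7-px dilation of the lumen–wall border to capture the
    IEL, and significance flagged at p ≤ 0.05 / 0.01 / 0.001 with a
    0.05–0.08 trend band.
    """

    voxel_size_um: float = 1.1
    central_window_n_slices: int = 200
    media_dilation_factor: float = 0.35
    iel_dilation_px: int = 7
    angular_samples: int = 720
    smooth_disk_px: int = 3
    min_lamella_px: int = 10
    threshold_method: str = "otsu"
    lamellae_threshold_method: str = "isodata"
    contour_spline_smoothing: float = 0.5
    centerline_smoothing: float = 0.0
    override_decay_slices: float = 10.0
    fallback_bright_quantile: float = 0.85
    radial_depth_px: int = 0  # 0 = auto (1.8 x measured wall thickness)
    thickness_step_px: float = 0.25
    break_threshold: float | None = None  # None = 0.75 x median surface grey
    break_relative_threshold: float = 0.75
    min_break_area_um2: float = 50.0
    significance_levels: tuple[float, float, float] = (0.05, 0.01, 0.001)
    trend_band: tuple[float, float] = (0.05, 0.08)
    reslice: bool = True
    max_failed_slice_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um: must be > 0")
        if not (0.0 < self.media_dilation_factor < 1.0):
            raise ValueError("media_dilation_factor: must be in (0, 1)")
        if self.central_window_n_slices < 1:
            raise ValueError("central_window_n_slices: must be >= 1")
        if self.iel_dilation_px < 0:
            raise ValueError("iel_dilation_px: must be >= 0")
        if self.angular_samples < 8:
            raise ValueError("angular_samples: must be >= 8")
        if not (0.0 < self.fallback_bright_quantile < 1.0):
            raise ValueError("fallback_bright_quantile: must be in (0, 1)")
        lo, hi = self.trend_band
        if not (0 <= lo < hi <= 1):
            raise ValueError("trend_band: must satisfy 0 <= low < high <= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML/JSON config file; absent keys take their defaults.

    Unknown keys and invariant violations are rejected with the
    offending key named.
    """
    cfg = PipelineConfig()
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        valid = set(cfg.__dataclass_fields__)
        for key, value in raw.items():
            if key not in valid:
                raise ValueError(f"unknown config key: {key!r}")
            fld = cfg.__dataclass_fields__[key]
            if isinstance(getattr(cfg, key), tuple) and isinstance(value, list):
                value = tuple(value)
            setattr(cfg, key, value)
    cfg.validate()
    return cfg


def config_summary(cfg: PipelineConfig) -> str:
    """Effective configuration as a stable JSON string (for run logs)."""
    return json.dumps(cfg.to_dict(), sort_keys=True, default=list)
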