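"""End-to-end runs: phantom or TIFF stack → segmentation → geometry →
morphometry / IEL surface → tables, plus synthetic-cohort group
comparisons.  Every run writes a manifest (config snapshot, input
checksums, per-slice provenance, output inventory, timings) so that a
rerun with the same config and seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import geometry as geo
from . import iel as iel_mod
from . import morphometry as mm
from . import segmentation as sg
from .io import PipelineConfig, VoxelGrid3D, read_stack, sha256_of_file, write_stack
from .phantom import PhantomSpec, generate_phantom
from .stats import compare_groups

__all__ = [
    "RunManifest",
    "MorphometryRun",
    "run_morphometry",
    "run_iel",
    "run_group_comparison",
]

log = logging.getLogger("aortamorph")


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_checksums: dict
    slice_provenance: dict
    timings_s: dict
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "seed": self.seed,
                    "input_checksums": self.input_checksums,
                    "slice_provenance": self.slice_provenance,
                    "timings_s": {k: round(v, 3) for k, v in self.timings_s.items()},
                    "outputs": self.outputs,
                },
                fh,
                indent=2,
                sort_keys=True,
                default=str,
            )


def _load_input(
    config: PipelineConfig, stack: VoxelGrid3D | str | Path | None, spec: PhantomSpec | None
):
    checksums = {}
    truth = None
    if spec is not None:
        grid, truth = generate_phantom(spec)
        checksums["phantom_spec"] = str(sorted(spec.__dict__.items()))
    elif isinstance(stack, VoxelGrid3D):
        grid = stack
    elif stack is not None:
        grid = read_stack(stack, config.voxel_size_um)
        p = Path(stack)
        if p.is_file():
            checksums[p.name] = sha256_of_file(p)
    else:
        raise ValueError("provide a stack or a phantom spec")
    return grid, truth, checksums


def _segment_stack(grid: VoxelGrid3D, config: PipelineConfig, window: range):
    """Segment every slice in the window; failures degrade gracefully."""
    segs: dict[int, sg.SliceSegmentation] = {}
    failures: dict[int, str] = {}
    last_centroid = None
    for z in window:
        try:
            seed = None
            if last_centroid is not None:
                seed = (int(round(last_centroid[0])), int(round(last_centroid[1])))
            seg = sg.segment_slice(grid.data[z], config, fallback_seed=seed)
            segs[z] = seg
            last_centroid = seg.lumen_centroid
        except sg.SegmentationError as exc:
            failures[z] = f"{type(exc).__name__}: {exc}"
            log.warning("slice %d failed: %s", z, exc)
    n = len(window)
    if n and len(failures) > config.max_failed_slice_fraction * n:
        detail = "; ".join(f"slice {z}: {msg}" for z, msg in sorted(failures.items()))
        raise RuntimeError(
            f"{len(failures)}/{n} slices failed segmentation (tolerance "
            f"{config.max_failed_slice_fraction:.0%}): {detail}"
        )
    return segs, failures


def _measure_slice(
    grid: VoxelGrid3D, z: int, seg: sg.SliceSegmentation, config: PipelineConfig
) -> mm.MorphometryRecord:
    vx = grid.voxel_size_um
    diameter, _ = mm.lumen_diameter(seg.lumen_contour, vx)
    if seg.provenance == "fallback" or seg.media_mask is None:
        return mm.MorphometryRecord(
            slice_index=z,
            lumen_diameter_um=diameter,
            media_area_um2=None,
            lamellae_area_um2=None,
            interlamellar_area_um2=None,
            lamellae_pct=None,
            thickness=None,
            provenance=seg.provenance,
        )
    pct, lam_area, inter_area = mm.lamellae_fraction(seg.lamellae_mask, seg.media_mask, vx)
    r_lumen = geo.contour_radius(seg.lumen_contour, seg.lumen_centroid, config.angular_samples)
    r_smooth = geo.smooth_radius_periodic(r_lumen, config.contour_spline_smoothing)
    thickness = mm.media_thickness(
        seg.media_mask,
        seg.lumen_centroid,
        r_smooth,
        vx,
        step_px=config.thickness_step_px,
    )
    return mm.MorphometryRecord(
        slice_index=z,
        lumen_diameter_um=diameter,
        media_area_um2=mm.cross_sectional_area(seg.media_mask, vx),
        lamellae_area_um2=lam_area,
        interlamellar_area_um2=inter_area,
        lamellae_pct=pct,
        thickness=thickness,
        provenance=seg.provenance,
    )


@dataclass
class MorphometryRun:
    records: list[mm.MorphometryRecord]
    summary: mm.StackSummary
    manifest: RunManifest
    table: pd.DataFrame
    segmentations: dict[int, sg.SliceSegmentation]
    window: range
    grid: VoxelGrid3D
    truth: object | None = None


def run_morphometry(
    config: PipelineConfig,
    stack: VoxelGrid3D | str | Path | None = None,
    spec: PhantomSpec | None = None,
    output_dir: str | Path | None = None,
    reslice: bool | None = None,
) -> MorphometryRun:
    """Full transverse morphometry of one stack.

    Stages: (optional) orthogonal reslicing to the vessel axis → central
    window selection → per-slice segmentation (watershed fallback on
    open walls) → virtual-opening morphometry → stack summary.
    """
    config.validate()
    t_all = time.time()
    timings = {}
    grid, truth, checksums = _load_input(config, stack, spec)
    if reslice is None:
        reslice = config.reslice

    if reslice:
        t0 = time.time()
        pre_window = range(grid.n_slices)
        pre_segs = {}
        for z in pre_window:
            try:
                wall = sg.segment_wall(grid.data[z], smooth_disk_px=config.smooth_disk_px)
                lumen, _ = sg.segment_lumen(wall)
                pre_segs[z] = lumen
            except sg.SegmentationError:
                continue
        if len(pre_segs) >= 4:
            zs = np.array(sorted(pre_segs))
            centerline = geo.compute_centerline(
                [pre_segs[z] for z in zs],
                smoothing=config.centerline_smoothing,
                z_values=zs.astype(float),
            )
            grid = geo.reslice_orthogonal(grid, centerline)
        else:
            log.warning("too few segmentable slices for reslicing; skipping")
        timings["reslice"] = time.time() - t0

    n_window = min(config.central_window_n_slices, grid.n_slices)
    window = geo.select_central_window(grid.n_slices, n_window)
    log.info("central window: slices %d..%d", window.start, window.stop - 1)

    t0 = time.time()
    segs, failures = _segment_stack(grid, config, window)
    timings["segmentation"] = time.time() - t0

    t0 = time.time()
    records = [_measure_slice(grid, z, segs[z], config) for z in sorted(segs)]
    summary = mm.summarize_stack(records)
    timings["morphometry"] = time.time() - t0
    timings["total"] = time.time() - t_all

    provenance = {str(z): segs[z].provenance for z in sorted(segs)}
    provenance.update({str(z): f"failed: {msg}" for z, msg in failures.items()})
    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        input_checksums=checksums,
        slice_provenance=provenance,
        timings_s=timings,
    )
    table = mm.records_to_frame(records)

    run = MorphometryRun(
        records=records,
        summary=summary,
        manifest=manifest,
        table=table,
        segmentations=segs,
        window=window,
        grid=grid,
        truth=truth,
    )
    if output_dir is not None:
        _write_morphometry_outputs(run, Path(output_dir))
    return run


def _float_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.6g")


def _write_morphometry_outputs(run: MorphometryRun, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _float_csv(run.table, outdir / "per_slice.csv")
    run.summary.as_frame().to_csv(outdir / "summary.csv", float_format="%.6g")
    thick = []
    for r in run.records:
        if r.thickness is None:
            continue
        for k, t in enumerate(r.thickness.samples_um):
            thick.append((r.slice_index, k, t))
    _float_csv(
        pd.DataFrame(thick, columns=["slice", "angle_sample", "thickness_um"]),
        outdir / "thickness_samples.csv",
    )
    from .plotting import plot_per_slice_traces, plot_thickness_histogram

    plot_per_slice_traces(run.table, outdir / "per_slice_traces.png")
    mid = run.records[len(run.records) // 2]
    if mid.thickness is not None:
        plot_thickness_histogram(mid.thickness, outdir / "thickness_histogram.png")
    run.manifest.outputs = [
        "per_slice.csv",
        "summary.csv",
        "thickness_samples.csv",
        "per_slice_traces.png",
        "thickness_histogram.png",
        "manifest.json",
    ]
    run.manifest.write(outdir / "manifest.json")
    log.info("effective config: %s", json.dumps(run.manifest.config, sort_keys=True, default=str))


@dataclass
class IELRun:
    surface: iel_mod.IELSurfaceImage
    regions: list[iel_mod.BreakRegion]
    break_pct: float
    manifest: RunManifest
    truth: object | None = None


def run_iel(
    config: PipelineConfig,
    stack: VoxelGrid3D | str | Path | None = None,
    spec: PhantomSpec | None = None,
    output_dir: str | Path | None = None,
    manual_break_mask: np.ndarray | None = None,
    window_n: int | None = None,
) -> IELRun:
    """IEL surface extraction and break quantification for one stack."""
    config.validate()
    t_all = time.time()
    grid, truth, checksums = _load_input(config, stack, spec)
    n = window_n if window_n is not None else grid.n_slices
    window = geo.select_central_window(grid.n_slices, min(n, grid.n_slices))

    segs, failures = _segment_stack(grid, config, window)
    zs = sorted(segs)
    if not zs:
        raise RuntimeError("no slice segmented; cannot build IEL surface")
    lumen_masks = [segs[z].lumen_mask for z in zs]
    wall_masks = [segs[z].wall_mask for z in zs]
    contours = [segs[z].lumen_contour for z in zs]
    shell = iel_mod.extract_iel(lumen_masks, wall_masks, config.iel_dilation_px)
    surface = iel_mod.enface_projection(
        grid.data[zs],
        shell,
        contours,
        grid.voxel_size_um,
        angular_samples=config.angular_samples,
        depth_px=max(12, config.iel_dilation_px * 2 + 2),
        contour_smoothing=config.contour_spline_smoothing,
    )
    regions, pct = iel_mod.quantify_breaks(
        surface,
        threshold=config.break_threshold,
        relative_threshold=config.break_relative_threshold,
        min_break_area_um2=config.min_break_area_um2,
        manual_mask=manual_break_mask,
    )
    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        input_checksums=checksums,
        slice_provenance={str(z): segs[z].provenance for z in zs},
        timings_s={"total": time.time() - t_all},
    )
    if output_dir is not None:
        outdir = Path(output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        from .plotting import plot_enface_surface

        write_stack(surface.data.astype(np.float32)[None], outdir / "iel_surface.tif")
        plot_enface_surface(surface, outdir / "iel_surface.png")
        _float_csv(iel_mod.breaks_to_frame(regions), outdir / "breaks.csv")
        with open(outdir / "break_summary.json", "w") as fh:
            json.dump(
                {"break_pct": pct, "n_breaks": len(regions)}, fh, indent=2, sort_keys=True
            )
        manifest.outputs = [
            "iel_surface.tif",
            "iel_surface.png",
            "breaks.csv",
            "break_summary.json",
            "manifest.json",
        ]
        manifest.write(outdir / "manifest.json")
    return IELRun(surface=surface, regions=regions, break_pct=pct, manifest=manifest, truth=truth)


def run_group_comparison(
    summaries: pd.DataFrame,
    parameters: list[str] | None = None,
    config: PipelineConfig | None = None,
    output_path: str | Path | None = None,
) -> pd.DataFrame:
    """All pairwise group comparisons for each morphometric parameter.

    ``summaries`` has one row per sample (animal/stack) with a ``group``
    column and one column per parameter (per-sample mean values).
    """
    cfg = config or PipelineConfig()
    if parameters is None:
        parameters = [c for c in summaries.columns if c != "group"]
    if summaries["group"].nunique() < 2:
        raise ValueError("need at least 2 groups")
    tables = [
        compare_groups(
            summaries, p, "group", cfg.significance_levels, cfg.trend_band
        )
        for p in parameters
    ]
    out = pd.concat(tables, ignore_index=True)
    if output_path is not None:
        Path(output_path).parent.mkdir(parents=True, exist_ok=True)
        _float_csv(out, Path(output_path))
    return out
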