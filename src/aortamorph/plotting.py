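"""Diagnostic plots: per-slice parameter traces, thickness histograms
with their Gaussian fits, and en-face IEL surface images."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_thickness_histogram",
    "plot_per_slice_traces",
    "plot_enface_surface",
]


def plot_thickness_histogram(thickness, path: str | Path) -> Path:
    """Histogram of one slice's thickness samples with the fitted Gaussian."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    centers = 0.5 * (thickness.bin_edges[:-1] + thickness.bin_edges[1:])
    width = np.diff(thickness.bin_edges)
    ax.bar(centers, thickness.counts, width=width, color="0.7", edgecolor="0.4")
    if thickness.sd_um > 0:
        x = np.linspace(thickness.bin_edges[0], thickness.bin_edges[-1], 200)
        amp = thickness.counts.max()
        y = amp * np.exp(-0.5 * ((x - thickness.mean_um) / thickness.sd_um) ** 2)
        ax.plot(x, y, "r-", lw=1.5)
    ax.set_xlabel("media thickness (µm)")
    ax.set_ylabel("count")
    ax.set_title(
        f"fit: {thickness.mean_um:.1f} ± {thickness.sd_um:.1f} µm "
        f"(n={thickness.n_samples})"
    )
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_per_slice_traces(table, path: str | Path) -> Path:
    """Per-slice traces of diameter, thickness, areas and lamellar %."""
    cols = [
        ("lumen_diameter_um", "diameter (µm)"),
        ("media_thickness_um", "media thickness (µm)"),
        ("media_area_um2", "media CSA (µm²)"),
        ("lamellae_pct", "lamellae (%)"),
    ]
    fig, axes = plt.subplots(len(cols), 1, figsize=(6, 2 * len(cols)), sharex=True)
    for ax, (col, label) in zip(np.atleast_1d(axes), cols):
        ax.plot(table["slice"], table[col], ".-", ms=3)
        ax.set_ylabel(label, fontsize=8)
    np.atleast_1d(axes)[-1].set_xlabel("slice")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_enface_surface(surface, path: str | Path) -> Path:
    """En-face IEL surface (axial x circumferential), breaks appear dark."""
    fig, ax = plt.subplots(figsize=(8, 3))
    img = np.where(surface.valid, surface.data, np.nan)
    ax.imshow(
        img,
        cmap="gray",
        aspect="auto",
        extent=(0, 360, surface.data.shape[0], 0),
        interpolation="nearest",
    )
    ax.set_xlabel("circumference (deg)")
    ax.set_ylabel("slice")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
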