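"""Rendering of gridded fields and trajectory overviews.

Thin matplotlib wrappers; all statistics are computed elsewhere. Heatmaps of
focal-frame correlation fields carry an annulus marking the mean cell radius.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .correlation import BinnedField, mean_cell_radius
from .io_tracks import Trajectory

__all__ = ["plot_field", "plot_trajectories", "plot_heading_rose"]

_CMAPS = {
    "polar_corr": ("RdBu_r", (-1, 1)),
    "nematic_corr": ("RdBu_r", (-1, 1)),
    "frequency": ("viridis", (None, None)),
    "velocity_hist": ("viridis", (None, None)),
}


def plot_field(
    field: BinnedField,
    out_path: str | Path,
    title: str | None = None,
    cell_radius_um: float | None = None,
) -> Path:
    """Render a binned field as a heatmap PNG; returns the written path."""
    cmap, (vmin, vmax) = _CMAPS.get(field.kind, ("viridis", (None, None)))
    fig, ax = plt.subplots(figsize=(5, 4.2))
    ext = field.extent_um
    im = ax.imshow(
        field.stat.T,
        origin="lower",
        extent=(-ext, ext, -ext, ext),
        cmap=cmap,
        vmin=vmin,
        vmax=vmax,
    )
    if field.kind in ("polar_corr", "nematic_corr", "frequency"):
        r = cell_radius_um if cell_radius_um is not None else mean_cell_radius()
        ax.add_patch(plt.Circle((0, 0), r, fill=False, ls=":", color="gold", lw=1.5))
        ax.set_xlabel("front–back (µm)")
        ax.set_ylabel("left–right (µm)")
    else:
        ax.set_xlabel("vx (µm/h)")
        ax.set_ylabel("vy (µm/h)")
    fig.colorbar(im, ax=ax, label=field.kind)
    if title:
        ax.set_title(title)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_trajectories(
    tracks: Sequence[Trajectory], out_path: str | Path, title: str | None = None
) -> Path:
    """Overlay all trajectories colored by time."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for tr in tracks:
        ax.plot(tr.x_um, tr.y_um, lw=0.6, alpha=0.7)
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    if title:
        ax.set_title(title)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_heading_rose(thetas, out_path: str | Path, bins: int = 36) -> Path:
    """Polar histogram of heading angles (angular velocity distribution)."""
    t = np.asarray(thetas, dtype=float)
    t = t[np.isfinite(t)]
    fig = plt.figure(figsize=(4.5, 4.5))
    ax = fig.add_subplot(projection="polar")
    counts, edges = np.histogram(t, bins=bins, range=(-np.pi, np.pi))
    ax.bar((edges[:-1] + edges[1:]) / 2, counts, width=np.diff(edges), alpha=0.8)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
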