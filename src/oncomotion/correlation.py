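"""Spatial pairwise statistics in the focal cell's moving frame.

For every ordered pair of cells (i, j) observed in the same frame, the
neighbor's offset x_j − x_i is rotated into the focal cell's frame — "front"
along the focal heading ω_i, "left" along the heading rotated +90° — and the
heading difference Δθ = θ_j − θ_i is wrapped to (−π, π]. Pooling pairs over
frames gives gridded maps over relative position:

* polar (direction) correlation: per-bin mean of cos Δθ (+1 synchronous,
  −1 opposing);
* nematic correlation: per-bin mean of cos 2Δθ (+1 for parallel AND
  antiparallel alignment — the bidirectional signature of streams);
* relative-position frequency: per-bin pair probability;

plus a 2-D velocity-vector histogram over all cell-time samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd

__all__ = [
    "BinnedField",
    "build_pairs",
    "polar_correlation_map",
    "nematic_correlation_map",
    "relative_position_map",
    "velocity_heatmap",
    "mean_cell_radius",
]

#: default cell radius (µm) when the tracking export has no size column;
#: half the 20 µm detection blob diameter
DEFAULT_CELL_RADIUS_UM = 10.0


@dataclass
class BinnedField:
    """A statistic binned on a 2-D grid, with per-bin counts and a mask.

    ``stat`` is NaN wherever ``counts < min_count`` (for correlation kinds)
    or outside the data support (frequency kinds). Axis convention: row index
    = first axis bins, column index = second axis bins; ``extent`` gives
    (min, max) shared by both axes.
    """

    kind: str  # polar_corr | nematic_corr | frequency | velocity_hist
    extent_um: float
    bin_um: float
    stat: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    min_count: int = 0

    @property
    def edges(self) -> np.ndarray:
        return np.arange(-self.extent_um, self.extent_um + self.bin_um / 2, self.bin_um)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return (e[:-1] + e[1:]) / 2

    def to_files(self, stem: str | Path) -> tuple[Path, Path]:
        """Write the grid as a CSV matrix plus a JSON sidecar of axes/metadata."""
        stem = Path(stem)
        csv_path = stem.with_suffix(".csv")
        json_path = stem.with_suffix(".json")
        np.savetxt(csv_path, self.stat, delimiter=",", fmt="%.10g")
        sidecar = {
            "kind": self.kind,
            "extent_um": self.extent_um,
            "bin_um": self.bin_um,
            "min_count": self.min_count,
            "n_bins": int(self.stat.shape[0]),
            "axis_centers_um": [float(c) for c in self.centers],
            "total_count": int(self.counts.sum()),
        }
        json_path.write_text(json.dumps(sidecar, indent=2))
        return csv_path, json_path


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return np.mod(a + np.pi, 2 * np.pi) - np.pi


def build_pairs(samples: pd.DataFrame, r_max_um: float = 150.0) -> pd.DataFrame:
    """All ordered same-frame cell pairs within ``r_max_um``, in focal frames.

    ``samples`` is the kinematics table (needs frame, x_um, y_um, theta_rad);
    rows with undefined heading are excluded. Returns columns
    focal_id, neighbor_id, frame, rel_front_um, rel_left_um, dtheta_rad.
    Frames with fewer than two cells contribute nothing.
    """
    ok = samples.dropna(subset=["theta_rad"])
    chunks = []
    for frame, grp in ok.groupby("frame", sort=True):
        n = len(grp)
        if n < 2:
            continue
        x = grp["x_um"].to_numpy(float)
        y = grp["y_um"].to_numpy(float)
        th = grp["theta_rad"].to_numpy(float)
        ids = grp["track_id"].to_numpy()
        dx = x[None, :] - x[:, None]  # [focal, neighbor]
        dy = y[None, :] - y[:, None]
        dist2 = dx**2 + dy**2
        i, j = np.nonzero((dist2 <= r_max_um**2) & ~np.eye(n, dtype=bool))
        if i.size == 0:
            continue
        c, s = np.cos(th[i]), np.sin(th[i])
        d_x, d_y = dx[i, j], dy[i, j]
        chunks.append(
            pd.DataFrame(
                {
                    "focal_id": ids[i],
                    "neighbor_id": ids[j],
                    "frame": frame,
                    "rel_front_um": c * d_x + s * d_y,
                    "rel_left_um": -s * d_x + c * d_y,
                    "dtheta_rad": _wrap_angle(th[j] - th[i]),
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=["focal_id", "neighbor_id", "frame", "rel_front_um", "rel_left_um", "dtheta_rad"]
        )
    return pd.concat(chunks, ignore_index=True)


def _binned_mean(
    pairs: pd.DataFrame,
    values: np.ndarray,
    kind: str,
    extent_um: float,
    bin_um: float,
    min_count: int,
) -> BinnedField:
    edges = np.arange(-extent_um, extent_um + bin_um / 2, bin_um)
    xy = (pairs["rel_front_um"].to_numpy(float), pairs["rel_left_um"].to_numpy(float))
    counts, _, _ = np.histogram2d(*xy, bins=(edges, edges))
    sums, _, _ = np.histogram2d(*xy, bins=(edges, edges), weights=values)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(counts >= max(min_count, 1), sums / counts, np.nan)
    return BinnedField(kind, extent_um, bin_um, stat, counts.astype(np.int64), min_count)


def polar_correlation_map(
    pairs: pd.DataFrame,
    extent_um: float = 100.0,
    bin_um: float = 5.0,
    min_count: int = 10,
) -> BinnedField:
    """Per-bin mean of cos Δθ over relative position, pooled over frames."""
    return _binned_mean(
        pairs, np.cos(pairs["dtheta_rad"].to_numpy(float)),
        "polar_corr", extent_um, bin_um, min_count,
    )


def nematic_correlation_map(
    pairs: pd.DataFrame,
    extent_um: float = 100.0,
    bin_um: float = 5.0,
    min_count: int = 10,
) -> BinnedField:
    """Per-bin mean of cos 2Δθ: +1 for both parallel and antiparallel pairs."""
    return _binned_mean(
        pairs, np.cos(2.0 * pairs["dtheta_rad"].to_numpy(float)),
        "nematic_corr", extent_um, bin_um, min_count,
    )


def relative_position_map(
    pairs: pd.DataFrame,
    extent_um: float = 100.0,
    bin_um: float = 5.0,
    per_area: bool = False,
) -> BinnedField:
    """Probability of finding a neighbor at each relative position.

    Counts are normalized by the total number of in-grid pairs so the grid
    sums to 1; with ``per_area`` the result is a probability density per µm²
    instead.
    """
    edges = np.arange(-extent_um, extent_um + bin_um / 2, bin_um)
    counts, _, _ = np.histogram2d(
        pairs["rel_front_um"].to_numpy(float),
        pairs["rel_left_um"].to_numpy(float),
        bins=(edges, edges),
    )
    total = counts.sum()
    if total == 0:
        raise ValueError("no pairs fall inside the grid")
    prob = counts / total
    if per_area:
        prob = prob / bin_um**2
    return BinnedField("frequency", extent_um, bin_um, prob, counts.astype(np.int64), 0)


def velocity_heatmap(
    samples: pd.DataFrame, v_extent: float = 50.0, v_bin: float = 2.0
) -> BinnedField:
    """2-D frequency histogram of (vx, vy) over all cell-time samples.

    A flock shows one off-center mode, a stream two antipodal modes, a swarm
    a ring/disc centered at the origin. Normalized to total frequency 1
    (samples outside the extent are clipped into the edge bins so nothing is
    lost).
    """
    if len(samples) == 0:
        raise ValueError("no samples")
    edges = np.arange(-v_extent, v_extent + v_bin / 2, v_bin)
    vx = np.clip(samples["vx"].to_numpy(float), -v_extent, v_extent)
    vy = np.clip(samples["vy"].to_numpy(float), -v_extent, v_extent)
    counts, _, _ = np.histogram2d(vx, vy, bins=(edges, edges))
    return BinnedField(
        "velocity_hist", v_extent, v_bin, counts / counts.sum(), counts.astype(np.int64), 0
    )


def mean_cell_radius(radii_um=None) -> float:
    """Mean cell radius (µm) used to annotate correlation maps.

    Uses per-cell size estimates when the tracking export provides them;
    otherwise falls back to half the 20 µm detection blob size.
    """
    if radii_um is None:
        return DEFAULT_CELL_RADIUS_UM
    r = np.asarray(radii_um, dtype=float)
    if r.size == 0:
        return DEFAULT_CELL_RADIUS_UM
    return float(r.mean())
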