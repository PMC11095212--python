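"""Trajectory smoothing and velocity estimation.

Raw single-particle tracks are jittery at the detection scale; positions are
smoothed with a truncated discrete Gaussian kernel (default sigma = 2 frames
over a 9-point stencil) and velocities are then taken by central finite
differences on the smoothed positions. Speeds are reported in µm h⁻¹ and
headings as theta = atan2(vy, vx) in (−π, π]; the velocity decomposes as
v = c (cos θ, sin θ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_tracks import AcquisitionMeta, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "KernelSpec",
    "gaussian_kernel",
    "smooth_trajectory",
    "segment_trajectory",
    "estimate_velocity",
    "compute_kinematics",
    "speed_summary",
]

#: columns of the per-sample kinematics table
SAMPLE_COLUMNS = [
    "track_id", "frame", "t_min", "x_um", "y_um",
    "vx", "vy", "speed_um_per_h", "theta_rad",
]


@dataclass(frozen=True)
class KernelSpec:
    """Discrete Gaussian smoothing kernel.

    ``sigma_frames`` is in frame units (the kernel is dimensionless on the
    sample index); ``stencil_points`` is the odd window length, so the
    default 9-point stencil spans offsets −4..4, i.e. ±2σ at σ = 2.
    """

    sigma_frames: float = 2.0
    stencil_points: int = 9

    def __post_init__(self) -> None:
        if self.sigma_frames <= 0:
            raise ValueError("sigma_frames must be > 0")
        if self.stencil_points < 3 or self.stencil_points % 2 == 0:
            raise ValueError("stencil_points must be odd and >= 3")


def gaussian_kernel(spec: KernelSpec) -> np.ndarray:
    """Normalized truncated Gaussian weights w_k ∝ exp(−k²/2σ²), k = −h..h."""
    h = (spec.stencil_points - 1) // 2
    k = np.arange(-h, h + 1, dtype=float)
    w = np.exp(-(k**2) / (2.0 * spec.sigma_frames**2))
    return w / w.sum()


def _smooth_series(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    # renormalized truncated kernel at the ends: divide by the local weight
    # mass so boundary windows still average to weight 1. Centered slice of
    # the full convolution (np.convolve 'same' misbehaves for tracks shorter
    # than the stencil).
    h = (len(w) - 1) // 2
    num = np.convolve(x, w, mode="full")[h: h + len(x)]
    den = np.convolve(np.ones_like(x), w, mode="full")[h: h + len(x)]
    return num / den


def smooth_trajectory(traj: Trajectory, kernel: KernelSpec | None = None) -> Trajectory:
    """Smooth a trajectory's coordinates with the discrete Gaussian kernel.

    The window is truncated and renormalized at track ends (no padding, no
    shortening), so output length, frames and track id match the input.
    Constant tracks are preserved exactly and, away from the ends, so are
    affine (uniform-velocity) tracks, because the kernel is symmetric.
    """
    kernel = kernel or KernelSpec()
    if len(traj) < 2:
        raise ValueError("trajectory too short to smooth")
    w = gaussian_kernel(kernel)
    return traj.replace_coords(_smooth_series(traj.x_um, w), _smooth_series(traj.y_um, w))


def segment_trajectory(
    traj: Trajectory, gap_policy: str = "bridge1", min_points: int = 2
) -> list[Trajectory]:
    """Split a trajectory at detection gaps.

    ``bridge1``: a single missed frame (frame step of 2) is bridged — the
    actual time difference is carried into the velocity estimate — while
    gaps of two or more frames split the track. ``split``: any gap splits.
    Segments shorter than ``min_points`` are dropped.
    """
    if gap_policy not in ("bridge1", "split"):
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    max_step = 2 if gap_policy == "bridge1" else 1
    steps = np.diff(traj.frames)
    cut = np.nonzero(steps > max_step)[0] + 1
    if len(cut) == 0:
        return [traj] if len(traj) >= min_points else []
    segments = []
    for idx in np.split(np.arange(len(traj)), cut):
        if len(idx) >= min_points:
            segments.append(
                Trajectory(
                    traj.track_id,
                    traj.frames[idx],
                    traj.x_um[idx],
                    traj.y_um[idx],
                    traj.frame_interval_min,
                )
            )
    if cut.size:
        logger.info(
            "track %d: split into %d segment(s) at gaps", traj.track_id, len(segments)
        )
    return segments


def estimate_velocity(traj: Trajectory, meta: AcquisitionMeta) -> pd.DataFrame:
    """Per-sample velocity, speed and heading from a (smoothed) trajectory.

    Interior samples use the central difference
    ``v(t_i) = (x_{i+1} − x_{i−1}) / (t_{i+1} − t_{i−1})``; the endpoints use
    one-sided differences. Time is in minutes, so velocities are scaled by 60
    to µm h⁻¹. Zero-velocity samples get ``theta_rad = NaN`` and are excluded
    from angular statistics downstream.
    """
    n = len(traj)
    t = traj.frames.astype(float) * meta.frame_interval_min
    if n < 3:
        logger.warning("track %d: length %d < 3, endpoint differences only", traj.track_id, n)
    vx = np.empty(n)
    vy = np.empty(n)
    vx[0] = (traj.x_um[1] - traj.x_um[0]) / (t[1] - t[0])
    vy[0] = (traj.y_um[1] - traj.y_um[0]) / (t[1] - t[0])
    vx[-1] = (traj.x_um[-1] - traj.x_um[-2]) / (t[-1] - t[-2])
    vy[-1] = (traj.y_um[-1] - traj.y_um[-2]) / (t[-1] - t[-2])
    if n > 2:
        dt = t[2:] - t[:-2]
        vx[1:-1] = (traj.x_um[2:] - traj.x_um[:-2]) / dt
        vy[1:-1] = (traj.y_um[2:] - traj.y_um[:-2]) / dt
    vx *= 60.0  # µm/min -> µm/h
    vy *= 60.0
    speed = np.hypot(vx, vy)
    theta = np.where(speed > 0, np.arctan2(vy, vx), np.nan)
    return pd.DataFrame(
        {
            "track_id": traj.track_id,
            "frame": traj.frames,
            "t_min": t,
            "x_um": traj.x_um,
            "y_um": traj.y_um,
            "vx": vx,
            "vy": vy,
            "speed_um_per_h": speed,
            "theta_rad": theta,
        }
    )


def compute_kinematics(
    tracks: Iterable[Trajectory],
    meta: AcquisitionMeta,
    kernel: KernelSpec | None = None,
    gap_policy: str = "bridge1",
    min_points: int = 10,
) -> pd.DataFrame:
    """Full smoothing + velocity stage over a track collection.

    Each track is split at detection gaps per ``gap_policy``, each surviving
    segment (length >= ``min_points``) is smoothed and differentiated, and
    the per-sample rows are concatenated into one table.
    """
    kernel = kernel or KernelSpec()
    frames = []
    for tr in tracks:
        for seg in segment_trajectory(tr, gap_policy, min_points):
            frames.append(estimate_velocity(smooth_trajectory(seg, kernel), meta))
    if not frames:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def speed_summary(
    samples: pd.DataFrame | Sequence[float], bin_width: float = 1.0
) -> dict:
    """Pooled cell-time speed distribution: mean, sd, histogram.

    Accepts the kinematics table or a bare speed sequence. All retained
    samples are pooled (no per-cell averaging).
    """
    if isinstance(samples, pd.DataFrame):
        speeds = samples["speed_um_per_h"].to_numpy(float)
    else:
        speeds = np.asarray(samples, dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if speeds.size == 0:
        raise ValueError("no speed samples")
    hi = max(bin_width, float(np.ceil(speeds.max() / bin_width)) * bin_width)
    edges = np.arange(0.0, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(speeds, bins=edges)
    return {
        "n": int(speeds.size),
        "mean": float(speeds.mean()),
        "sd": float(speeds.std(ddof=0)),
        "hist_counts": counts,
        "hist_edges": edges,
    }
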