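"""Self-propelled-particle generator for flock, stream and swarm regimes.

Stands in for time-lapse movies of adherent glioma cells: each simulated cell
carries a base heading set by the regime — one shared direction (flock), one
of two antiparallel directions (stream), or none (swarm) — plus angular
noise, and advances at a lognormally distributed speed with reflecting
boundaries. Output can be written as the tracking-export CSV dialect the
ingest module reads, so every pipeline stage is testable without microscopy
data.

Heading model
-------------
flock/stream: θ_i(t) = base_i + ξ_i(t), with ξ a stationary AR(1) process of
marginal standard deviation ``angular_noise_sigma_rad`` (per-frame
autocorrelation 0.7), so headings fluctuate but keep the regime's marginal.
swarm: θ_i(t) is a wrapped random walk with uniform initial condition and a
large per-frame step (``swarm_diffusion_rad_per_frame``, default 2 rad —
cells repolarize within about one frame, as disordered migration shows);
the uniform law is exactly stationary under additive circular noise, so
pooled headings stay uniform, and the fast mixing keeps successive headings
of one cell nearly independent.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_tracks import AcquisitionMeta, Trajectory, write_spots

__all__ = [
    "SyntheticRegimeConfig",
    "PerturbationEvent",
    "simulate",
    "write_fixture",
    "density_series",
]

REGIMES = ("flock", "stream", "swarm")
_AR1_COEFF = 0.7  # per-frame autocorrelation of the angular noise


@dataclass(frozen=True)
class SyntheticRegimeConfig:
    """Generator settings for one synthetic movie.

    Defaults mirror the acquisition they emulate: an 850.19 µm square field
    imaged every 10 min, cells around 12 µm h⁻¹ with right-skewed speeds
    (cv 0.3) and moderate angular noise.
    """

    regime: str = "swarm"
    n_cells: int = 150
    field_um: tuple[float, float] = (850.19, 850.19)
    frame_interval_min: float = 10.0
    n_frames: int = 60
    mean_speed_um_per_h: float = 12.0
    speed_cv: float = 0.3
    angular_noise_sigma_rad: float = 0.3
    regime_mu_rad: float = 0.0
    swarm_diffusion_rad_per_frame: float = 2.0
    detection_dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.n_cells < 1 or self.n_frames < 2:
            raise ValueError("need n_cells >= 1 and n_frames >= 2")
        if min(self.field_um) <= 0 or self.frame_interval_min <= 0:
            raise ValueError("field and frame interval must be positive")
        if self.mean_speed_um_per_h <= 0 or self.speed_cv < 0:
            raise ValueError("mean speed must be positive, cv non-negative")
        if self.angular_noise_sigma_rad < 0:
            raise ValueError("angular noise must be non-negative")
        if self.swarm_diffusion_rad_per_frame < 0:
            raise ValueError("swarm diffusion must be non-negative")
        if not (0.0 <= self.detection_dropout_prob <= 0.5):
            raise ValueError("dropout must be in [0, 0.5]")
        step = self.mean_speed_um_per_h * self.frame_interval_min / 60.0
        if step > min(self.field_um):
            raise ValueError("per-frame step length exceeds field size")

    @property
    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            pixel_size_um=0.415,
            frame_interval_min=self.frame_interval_min,
            field_width_um=self.field_um[0],
            field_height_um=self.field_um[1],
        )


@dataclass(frozen=True)
class PerturbationEvent:
    """Mid-movie parameter change emulating a treatment addition."""

    at_frame: int
    mean_speed_um_per_h: float | None = None
    regime: str | None = None
    angular_noise_sigma_rad: float | None = None

    def __post_init__(self) -> None:
        if self.at_frame < 0:
            raise ValueError("at_frame must be >= 0")
        if self.regime is not None and self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")


def _base_headings(regime: str, mu: float, n: int, rng: np.random.Generator) -> np.ndarray:
    if regime == "flock":
        return np.full(n, mu)
    if regime == "stream":
        sign = rng.random(n) < 0.5  # random half of cells per axis direction
        return np.where(sign, mu, mu + math.pi)
    return rng.uniform(-math.pi, math.pi, n)  # swarm


def _lognormal_speeds(mean: float, cv: float, size, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    s2 = math.log1p(cv**2)
    return rng.lognormal(math.log(mean) - s2 / 2.0, math.sqrt(s2), size)


def simulate(
    config: SyntheticRegimeConfig,
    events: Sequence[PerturbationEvent] = (),
) -> tuple[list[Trajectory], dict]:
    """Generate one synthetic movie; deterministic given ``config.seed``.

    Returns the trajectories plus a ground-truth record (regime, per-cell
    base headings, frame labels, config echo). Detections are dropped
    independently with ``detection_dropout_prob``; tracks left with fewer
    than two samples are discarded.
    """
    for ev in events:
        if not (0 <= ev.at_frame < config.n_frames):
            raise ValueError(f"event at_frame {ev.at_frame} outside [0, {config.n_frames})")
    rng = np.random.default_rng(config.seed)
    n, T = config.n_cells, config.n_frames
    W, H = config.field_um
    dt_h = config.frame_interval_min / 60.0

    regime = config.regime
    mean_speed = config.mean_speed_um_per_h
    sigma_ang = config.angular_noise_sigma_rad
    events_by_frame = {ev.at_frame: ev for ev in events}

    x = rng.uniform(0, W, n)
    y = rng.uniform(0, H, n)
    base = _base_headings(regime, config.regime_mu_rad, n, rng)
    # stationary AR(1) start so the marginal sd equals sigma from frame 0
    noise = rng.normal(0.0, sigma_ang, n) if sigma_ang > 0 else np.zeros(n)

    xs = np.empty((T, n))
    ys = np.empty((T, n))
    frame_regime: list[str] = []
    xs[0], ys[0] = x, y

    for t in range(T):
        if t in events_by_frame:
            ev = events_by_frame[t]
            if ev.mean_speed_um_per_h is not None:
                mean_speed = ev.mean_speed_um_per_h
            if ev.angular_noise_sigma_rad is not None:
                sigma_ang = ev.angular_noise_sigma_rad
            if ev.regime is not None and ev.regime != regime:
                regime = ev.regime
                base = _base_headings(regime, config.regime_mu_rad, n, rng)
        frame_regime.append(regime)
        if t == 0:
            continue
        if regime == "swarm":
            # wrapped random walk; uniform marginal is stationary
            if config.swarm_diffusion_rad_per_frame > 0:
                base = base + rng.normal(0.0, config.swarm_diffusion_rad_per_frame, n)
            theta = base
        else:
            if sigma_ang > 0:
                innov = rng.normal(0.0, sigma_ang * math.sqrt(1 - _AR1_COEFF**2), n)
                noise = _AR1_COEFF * noise + innov
            theta = base + noise
        speed = _lognormal_speeds(mean_speed, config.speed_cv, n, rng)
        x = x + speed * dt_h * np.cos(theta)
        y = y + speed * dt_h * np.sin(theta)
        # reflecting boundaries: fold position back and mirror the heading
        out_x = (x < 0) | (x > W)
        out_y = (y < 0) | (y > H)
        x = np.where(x < 0, -x, np.where(x > W, 2 * W - x, x))
        y = np.where(y < 0, -y, np.where(y > H, 2 * H - y, y))
        if out_x.any():
            base = np.where(out_x, math.pi - base, base)
            noise = np.where(out_x, -noise, noise)
        if out_y.any():
            base = np.where(out_y, -base, base)
            noise = np.where(out_y, -noise, noise)
        xs[t], ys[t] = x, y

    keep = (
        rng.random((T, n)) >= config.detection_dropout_prob
        if config.detection_dropout_prob > 0
        else np.ones((T, n), dtype=bool)
    )
    tracks: list[Trajectory] = []
    for i in range(n):
        fr = np.nonzero(keep[:, i])[0]
        if len(fr) < 2:
            continue
        tracks.append(
            Trajectory(i, fr, xs[fr, i], ys[fr, i], config.frame_interval_min)
        )
    truth = {
        "regime": config.regime,
        "frame_regime": frame_regime,
        "base_headings_rad": [
            float(np.mod(b + math.pi, 2 * math.pi) - math.pi) for b in base
        ],
        # json round-trip turns tuples into lists for clean (de)serialization
        "config": json.loads(json.dumps(dataclasses.asdict(config))),
        "n_tracks": len(tracks),
    }
    return tracks, truth


def write_fixture(
    tracks: Sequence[Trajectory],
    meta: AcquisitionMeta,
    out_dir: str | Path,
    truth: dict | None = None,
) -> dict[str, Path]:
    """Write a movie as tracking-export fixtures the ingest module reads.

    Emits ``spots.csv`` (positions in pixels at 0.415 µm/px), ``tracks.csv``
    (per-track spot counts), and when ground truth is given
    ``ground_truth.json`` plus a ``config.yaml`` echo.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "spots": out_dir / "spots.csv",
        "tracks": out_dir / "tracks.csv",
    }
    write_spots(tracks, meta, paths["spots"], coordinate_unit="px")
    stats = pd.DataFrame(
        {"TRACK_ID": [t.track_id for t in tracks], "NUMBER_SPOTS": [len(t) for t in tracks]}
    )
    stats.to_csv(paths["tracks"], index=False)
    if truth is not None:
        paths["ground_truth"] = out_dir / "ground_truth.json"
        paths["ground_truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
        paths["config"] = out_dir / "config.yaml"
        paths["config"].write_text(yaml.safe_dump(truth["config"], sort_keys=True))
    return paths


def density_series(
    base_config: SyntheticRegimeConfig,
    densities: Sequence[int],
    out_dir: str | Path,
    regimes: Sequence[str] | None = None,
) -> list[dict]:
    """Generate one fixture per cell density with a density→regime mapping.

    By default densities at or below the midpoint of the range get the swarm
    regime and the rest the stream regime, emulating the observed low-density
    dispersal versus high-density bidirectional organization. Per-fixture
    seeds are ``base_config.seed + index``.
    """
    densities = list(densities)
    if len(densities) < 2:
        raise ValueError("need at least two density levels")
    if regimes is None:
        mid = (min(densities) + max(densities)) / 2.0
        regimes = ["swarm" if d <= mid else "stream" for d in densities]
    if len(regimes) != len(densities):
        raise ValueError("regimes and densities must align")
    out_dir = Path(out_dir)
    results = []
    for idx, (dens, reg) in enumerate(zip(densities, regimes)):
        cfg = dataclasses.replace(
            base_config, n_cells=dens, regime=reg, seed=base_config.seed + idx
        )
        tracks, truth = simulate(cfg)
        paths = write_fixture(tracks, cfg.meta, out_dir / f"density_{dens}", truth)
        results.append({"density": dens, "regime": reg, "config": cfg, "paths": paths})
    return results
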