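"""End-to-end analysis pipeline: read → filter → smooth → kinematics →
per-window/per-zone classification and correlation fields → report.

A run is configured by a :class:`RunConfig` (loadable from YAML), executes
deterministically, and writes a per-sample kinematics table, gridded
correlation fields, and a JSON report (plus a Markdown summary). The report
carries provenance: a stable hash of the configuration and the package
version. Time windows are closed-open ``[t_start, t_end)`` in hours; zone
membership is evaluated per sample, so a track can contribute to several
zones over time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import (
    build_pairs,
    nematic_correlation_map,
    polar_correlation_map,
    relative_position_map,
    velocity_heatmap,
)
from .io_tracks import AcquisitionMeta, assign_zone, filter_tracks, read_spots, read_zones
from .kinematics import KernelSpec, compute_kinematics, speed_summary
from .patterns import classify

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "compare_runs", "report_to_markdown"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (YAML-serializable)."""

    spots_path: str
    out_dir: str
    zones_path: str | None = None
    coordinate_unit: str = "px"
    pixel_size_um: float = 0.415
    frame_interval_min: float = 10.0
    sigma_frames: float = 2.0
    stencil_points: int = 9
    min_points: int = 10
    gap_policy: str = "bridge1"
    windows_h: tuple[tuple[float, float], ...] | None = None
    n_min: int = 30
    grid_extent_um: float = 100.0
    grid_bin_um: float = 5.0
    grid_min_count: int = 10
    r_max_um: float = 150.0
    v_extent: float = 50.0
    v_bin: float = 2.0
    write_fields: bool = True
    speed_bin_width: float = 1.0

    def __post_init__(self) -> None:
        if self.windows_h is not None:
            object.__setattr__(
                self, "windows_h", tuple(tuple(float(v) for v in w) for w in self.windows_h)
            )
            for a, b in self.windows_h:
                if b <= a:
                    raise ValueError(f"window [{a}, {b}) is empty")
            spans = sorted(self.windows_h)
            for (a0, b0), (a1, b1) in zip(spans, spans[1:]):
                if a1 < b0:
                    raise ValueError("windows overlap")

    @property
    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(self.pixel_size_um, self.frame_interval_min)

    @property
    def kernel(self) -> KernelSpec:
        return KernelSpec(self.sigma_frames, self.stencil_points)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return json.loads(json.dumps(dataclasses.asdict(self)))

    def hash(self) -> str:
        """Stable hash of the canonical JSON serialization."""
        blob = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _classification_record(thetas: np.ndarray, n_min: int) -> dict | None:
    thetas = thetas[np.isfinite(thetas)]
    if thetas.size < n_min:
        return None
    res = classify(thetas, n_min=n_min)
    return {
        "label": res.label,
        "decisive": res.decisive,
        "n_headings": res.n,
        "fits": [
            {
                "model": f.model,
                "mu_rad": f.mu_rad,
                "sigma_rad": f.sigma_rad,
                "loglik": f.loglik,
                "aic": f.aic,
                "akaike_weight": f.akaike_weight,
            }
            for f in res.fits
        ],
    }


def _analyze_cell(
    sub: pd.DataFrame, cfg: RunConfig, field_dir: Path | None
) -> dict[str, Any]:
    """Statistics for one (window, zone) cell of the report structure."""
    rec: dict[str, Any] = {
        "n_tracks": int(sub["track_id"].nunique()),
        "n_samples": int(len(sub)),
        "n_zero_speed": int(sub["theta_rad"].isna().sum()),
    }
    if len(sub) == 0:
        rec.update(mean_speed=None, sd_speed=None, classification=None, insufficient_n=True)
        return rec
    ss = speed_summary(sub, cfg.speed_bin_width)
    rec["mean_speed"] = ss["mean"]
    rec["sd_speed"] = ss["sd"]
    rec["classification"] = _classification_record(sub["theta_rad"].to_numpy(float), cfg.n_min)
    rec["insufficient_n"] = rec["classification"] is None
    if field_dir is not None:
        field_dir.mkdir(parents=True, exist_ok=True)
        pairs = build_pairs(sub, cfg.r_max_um)
        rec["n_pairs"] = int(len(pairs))
        files: dict[str, str] = {}
        if len(pairs):
            for name, fld in (
                ("polar", polar_correlation_map(pairs, cfg.grid_extent_um, cfg.grid_bin_um, cfg.grid_min_count)),
                ("nematic", nematic_correlation_map(pairs, cfg.grid_extent_um, cfg.grid_bin_um, cfg.grid_min_count)),
                ("relpos", relative_position_map(pairs, cfg.grid_extent_um, cfg.grid_bin_um)),
            ):
                csv_p, _ = fld.to_files(field_dir / name)
                files[name] = str(csv_p)
        vh = velocity_heatmap(sub, cfg.v_extent, cfg.v_bin)
        csv_p, _ = vh.to_files(field_dir / "velocity")
        files["velocity"] = str(csv_p)
        rec["fields"] = files
    return rec


def run(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and write) the run report.

    Idempotent: re-running with the same config overwrites the same outputs
    with identical values.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    tracks = read_spots(config.spots_path, config.meta, config.coordinate_unit)
    logger.info("stage read: %d tracks", len(tracks))
    retained = filter_tracks(tracks, config.min_points)
    logger.info("stage filter: %d/%d tracks retained", len(retained), len(tracks))
    samples = compute_kinematics(
        retained, config.meta, config.kernel, config.gap_policy, config.min_points
    )
    logger.info("stage kinematics: %d samples", len(samples))

    zones = read_zones(config.zones_path) if config.zones_path else []
    if zones:
        samples["zone"] = [
            assign_zone(x, y, zones)
            for x, y in zip(samples["x_um"], samples["y_um"])
        ]
    else:
        samples["zone"] = None
    samples.to_csv(out_dir / "kinematics.csv", index=False, float_format="%.10g")

    if config.windows_h is None:
        t_end_h = float(samples["t_min"].max()) / 60.0 + 1e-9 if len(samples) else 0.0
        windows = [(0.0, max(t_end_h, 1e-9))]
    else:
        windows = [tuple(w) for w in config.windows_h]

    scopes = ["global"] + [z.name for z in zones]
    report_windows = []
    for w_i, (a_h, b_h) in enumerate(windows):
        in_w = samples[(samples["t_min"] >= a_h * 60.0) & (samples["t_min"] < b_h * 60.0)]
        zone_recs = {}
        for scope in scopes:
            sub = in_w if scope == "global" else in_w[in_w["zone"] == scope]
            field_dir = (
                out_dir / "fields" / f"window_{w_i}" / scope if config.write_fields and scope == "global" else None
            )
            zone_recs[scope] = _analyze_cell(sub.reset_index(drop=True), config, field_dir)
        report_windows.append({"window_h": [a_h, b_h], "zones": zone_recs})

    report = {
        "provenance": {
            "config_hash": config.hash(),
            "oncomotion_version": __version__,
        },
        "config": config.to_dict(),
        "n_tracks_raw": len(tracks),
        "n_tracks_retained": len(retained),
        "n_samples": int(len(samples)),
        "windows": report_windows,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "report.md").write_text(report_to_markdown(report))
    return report


def report_to_markdown(report: dict) -> str:
    """Human-readable summary of a run report."""
    lines = [
        "# Migration-pattern analysis report",
        "",
        f"- config hash: `{report['provenance']['config_hash']}`",
        f"- tracks: {report['n_tracks_retained']} retained of {report['n_tracks_raw']}",
        f"- samples: {report['n_samples']}",
        "",
        "| window (h) | zone | n tracks | n samples | mean speed (µm/h) | label | max AW |",
        "|---|---|---|---|---|---|---|",
    ]
    for w in report["windows"]:
        a, b = w["window_h"]
        for zone, rec in w["zones"].items():
            cls = rec.get("classification")
            label = cls["label"] if cls else "insufficient n"
            aw = f"{cls['fits'][0]['akaike_weight']:.3f}" if cls else "—"
            ms = f"{rec['mean_speed']:.2f}" if rec.get("mean_speed") is not None else "—"
            lines.append(
                f"| {a:g}–{b:g} | {zone} | {rec['n_tracks']} | {rec['n_samples']} | {ms} | {label} | {aw} |"
            )
    return "\n".join(lines) + "\n"


def compare_runs(report_a: dict, report_b: dict) -> dict:
    """Per-window/per-zone deltas between two run reports.

    Reports must share the window/zone structure. Returns mean-speed deltas
    (b − a) and flags label changes.
    """
    wa, wb = report_a["windows"], report_b["windows"]
    if len(wa) != len(wb):
        raise ValueError("window structure mismatch")
    cells = []
    for win_a, win_b in zip(wa, wb):
        if list(win_a["window_h"]) != list(win_b["window_h"]):
            raise ValueError("window bounds mismatch")
        if set(win_a["zones"]) != set(win_b["zones"]):
            raise ValueError("zone structure mismatch")
        for zone in win_a["zones"]:
            ra, rb = win_a["zones"][zone], win_b["zones"][zone]
            ca, cb = ra.get("classification"), rb.get("classification")
            la = ca["label"] if ca else None
            lb = cb["label"] if cb else None
            ma, mb = ra.get("mean_speed"), rb.get("mean_speed")
            cells.append(
                {
                    "window_h": list(win_a["window_h"]),
                    "zone": zone,
                    "mean_speed_delta": (mb - ma) if (ma is not None and mb is not None) else None,
                    "label_a": la,
                    "label_b": lb,
                    "label_changed": la != lb,
                }
            )
    return {"cells": cells, "n_label_changes": sum(c["label_changed"] for c in cells)}
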