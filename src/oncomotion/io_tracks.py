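"""Reading, validation and filtering of particle-tracking exports.

Supports the CSV dialect exported by the Fiji TrackMate plugin ("Spots" and
"Tracks Statistics" tables), including the v7 variant that inserts up to three
auxiliary non-data rows (units, localized names) directly after the header.
Coordinates are converted to micrometres on ingest; zones of interest are read
from a ``coordinates.json`` file holding rectangles or general polygons.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionMeta",
    "Trajectory",
    "Zone",
    "SchemaError",
    "ValidationError",
    "read_spots",
    "write_spots",
    "read_track_statistics",
    "filter_tracks",
    "read_zones",
    "assign_zone",
]


class SchemaError(ValueError):
    """A required column is missing or the table layout is unreadable."""


class ValidationError(ValueError):
    """The table parsed but its content violates an invariant."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Physical acquisition settings of a time-lapse movie.

    Parameters
    ----------
    pixel_size_um
        Edge length of one pixel in µm (0.415 for the 20x setup).
    frame_interval_min
        Minutes between consecutive frames; 10, 5 and 1.5 min are the
        typical acquisition intervals but any positive value is accepted.
    field_width_um, field_height_um
        Optional imaging-field extent in µm; when given, point coordinates
        are validated against it with one pixel of tolerance.
    """

    pixel_size_um: float = 0.415
    frame_interval_min: float = 10.0
    field_width_um: float | None = None
    field_height_um: float | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be strictly positive")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be strictly positive")
        for name in ("field_width_um", "field_height_um"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass(eq=False)
class Trajectory:
    """One cell's ordered (frame, x, y) samples in physical units.

    Frames are 0-based and strictly increasing; time is derived as
    ``t_min = frame * frame_interval_min`` (frame 0 is t = 0).
    """

    track_id: int
    frames: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    frame_interval_min: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        n = len(self.frames)
        if not (len(self.x_um) == len(self.y_um) == n):
            raise ValidationError("frames, x_um, y_um must have equal length")
        if n < 2:
            raise ValidationError(f"track {self.track_id}: length {n} < 2")
        if np.any(np.diff(self.frames) <= 0):
            raise ValidationError(f"track {self.track_id}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ValidationError(f"track {self.track_id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t_min(self) -> np.ndarray:
        return self.frames * self.frame_interval_min

    def replace_coords(self, x_um: np.ndarray, y_um: np.ndarray) -> "Trajectory":
        return Trajectory(self.track_id, self.frames.copy(), x_um, y_um, self.frame_interval_min)


@dataclass
class Zone:
    """Named region of interest; vertices in µm, image-plane coordinates."""

    name: str
    polygon: Polygon = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.polygon.exterior.coords) - 1 < 3:
            raise ValidationError(f"zone {self.name!r}: fewer than 3 vertices")
        if not self.polygon.is_valid:
            raise ValidationError(f"zone {self.name!r}: self-intersecting polygon")
        if self.polygon.area <= 0:
            raise ValidationError(f"zone {self.name!r}: degenerate polygon (area 0)")

    @property
    def area_um2(self) -> float:
        return self.polygon.area

    def contains(self, x_um: float, y_um: float) -> bool:
        # covers() is boundary-inclusive, unlike contains()
        return self.polygon.covers(Point(x_um, y_um))


# -- column resolution ------------------------------------------------------

_COLUMN_ALIASES = {
    "track_id": ("TRACK_ID", "track_id", "TrackID"),
    "frame": ("FRAME", "frame", "Frame"),
    "x": ("POSITION_X", "x", "X", "position_x"),
    "y": ("POSITION_Y", "y", "Y", "position_y"),
}


def _resolve_columns(columns: Sequence[str]) -> dict[str, str]:
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in columns:
                resolved[canonical] = alias
                break
        else:
            raise SchemaError(
                f"required column {aliases[0]!r} (or alias) not found; "
                f"available: {list(columns)}"
            )
    return resolved


def _read_trackmate_table(path: str | Path) -> pd.DataFrame:
    """Read a TrackMate-dialect CSV, skipping up to 3 auxiliary header rows.

    TrackMate v7 exports repeat the header as human-readable name, key and
    unit rows before the data; auto-detect by attempting a numeric parse of
    the rows following the header.
    """
    df = pd.read_csv(path, sep=",")
    n_aux = 0
    for i in range(min(3, len(df))):
        row = df.iloc[i]
        numeric = pd.to_numeric(row, errors="coerce")
        if numeric.isna().all() and row.notna().any():
            n_aux = i + 1
        else:
            break
    if n_aux:
        df = df.iloc[n_aux:].reset_index(drop=True)
        logger.info("skipped %d auxiliary header row(s) in %s", n_aux, path)
    return df


def read_spots(
    path: str | Path,
    meta: AcquisitionMeta,
    coordinate_unit: str = "px",
) -> list[Trajectory]:
    """Read a "Spots" table into trajectories grouped by track id.

    Parameters
    ----------
    path
        CSV with at least TRACK_ID, FRAME, POSITION_X, POSITION_Y columns.
    meta
        Acquisition settings; ``pixel_size_um`` scales pixel coordinates.
    coordinate_unit
        ``"px"`` if positions are in pixels (converted via pixel size),
        ``"um"`` if already in micrometres (passed through).

    Returns
    -------
    list of Trajectory, sorted by track id, each sorted by frame.
    """
    if coordinate_unit not in ("px", "um"):
        raise ValueError(f"coordinate_unit must be 'px' or 'um', got {coordinate_unit!r}")
    df = _read_trackmate_table(path)
    if df.empty:
        return []
    cols = _resolve_columns(list(df.columns))
    sub = df[[cols["track_id"], cols["frame"], cols["x"], cols["y"]]].copy()
    sub.columns = ["track_id", "frame", "x", "y"]
    # spots not yet linked into a track carry TRACK_ID = None/NaN; drop them
    sub = sub.dropna(subset=["track_id"])
    if sub.empty:
        return []
    for c in ("frame", "x", "y"):
        sub[c] = pd.to_numeric(sub[c], errors="raise")
    sub["track_id"] = pd.to_numeric(sub["track_id"], errors="raise").astype(np.int64)
    sub["frame"] = sub["frame"].astype(np.int64)

    dup = sub.duplicated(subset=["track_id", "frame"])
    if dup.any():
        tid, fr = sub.loc[dup.idxmax(), ["track_id", "frame"]]
        raise ValidationError(f"duplicate (track, frame) pair: track {tid}, frame {fr}")

    scale = meta.pixel_size_um if coordinate_unit == "px" else 1.0
    tol = meta.pixel_size_um  # one pixel of tolerance on field bounds
    out: list[Trajectory] = []
    for tid, grp in sub.groupby("track_id", sort=True):
        if not grp["frame"].is_monotonic_increasing:
            logger.warning("track %d: non-monotone frames, repaired by sorting", tid)
            grp = grp.sort_values("frame")
        x = grp["x"].to_numpy() * scale
        y = grp["y"].to_numpy() * scale
        if meta.field_width_um is not None and (
            x.min() < -tol or x.max() > meta.field_width_um + tol
        ):
            raise ValidationError(f"track {tid}: x outside field bounds")
        if meta.field_height_um is not None and (
            y.min() < -tol or y.max() > meta.field_height_um + tol
        ):
            raise ValidationError(f"track {tid}: y outside field bounds")
        out.append(Trajectory(int(tid), grp["frame"].to_numpy(), x, y, meta.frame_interval_min))
    return out


def write_spots(
    tracks: Iterable[Trajectory],
    meta: AcquisitionMeta,
    path: str | Path,
    coordinate_unit: str = "px",
) -> None:
    """Write trajectories as a "Spots" CSV in the dialect ``read_spots`` reads."""
    if coordinate_unit not in ("px", "um"):
        raise ValueError(f"coordinate_unit must be 'px' or 'um', got {coordinate_unit!r}")
    scale = 1.0 / meta.pixel_size_um if coordinate_unit == "px" else 1.0
    rows = []
    for tr in tracks:
        for f, x, y in zip(tr.frames, tr.x_um, tr.y_um):
            rows.append((tr.track_id, int(f), x * scale, y * scale))
    df = pd.DataFrame(rows, columns=["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"])
    df.to_csv(path, index=False, float_format="%.12g")


def read_track_statistics(path: str | Path) -> pd.DataFrame:
    """Read a "Tracks Statistics" table (TRACK_ID, NUMBER_SPOTS).

    Used only to cross-validate the retention filter against the tracker's
    own spot counts.
    """
    df = _read_trackmate_table(path)
    for col in ("TRACK_ID", "NUMBER_SPOTS"):
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found")
    out = df[["TRACK_ID", "NUMBER_SPOTS"]].apply(pd.to_numeric, errors="raise")
    return out.astype(np.int64)


def filter_tracks(tracks: Sequence[Trajectory], min_points: int = 10) -> list[Trajectory]:
    """Retain only tracks with at least ``min_points`` samples (inclusive).

    The default of 10 follows the tracking protocol's retention rule for
    short spurious tracks. Order is preserved; the input is not modified.
    """
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    return [t for t in tracks if len(t) >= min_points]


def read_zones(path: str | Path) -> list[Zone]:
    """Read a ``coordinates.json`` zone-definition file.

    Schema::

        {"unit": "um", "zones": [
            {"name": "A", "rect": [x_min, y_min, x_max, y_max]},
            {"name": "B", "polygon": [[x, y], ...]}
        ]}
    """
    with open(path) as fh:
        doc = json.load(fh)
    unit = doc.get("unit", "um")
    if unit != "um":
        raise ValidationError(f"unsupported zone unit {unit!r} (expected 'um')")
    zones: list[Zone] = []
    seen: set[str] = set()
    for entry in doc.get("zones", []):
        name = entry["name"]
        if name in seen:
            raise ValidationError(f"duplicate zone name {name!r}")
        seen.add(name)
        if "rect" in entry:
            x0, y0, x1, y1 = entry["rect"]
            poly = Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])
        elif "polygon" in entry:
            poly = Polygon([tuple(v) for v in entry["polygon"]])
        else:
            raise SchemaError(f"zone {name!r}: needs 'rect' or 'polygon'")
        zones.append(Zone(name, poly))
    return zones


def assign_zone(x_um: float, y_um: float, zones: Sequence[Zone]) -> str | None:
    """Return the first zone (file order) containing the point, else None.

    Boundary points count as inside; a point on a shared edge goes to the
    earlier zone in file order (documented tie-break).
    """
    for z in zones:
        if z.contains(x_um, y_um):
            return z.name
    return None
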