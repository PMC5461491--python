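"""Readers and writers for tracking tables, nest geometry and GC peak tables.

File formats are deliberately plain text:

* tracking — CSV with header ``time_s,ant_id,x_cm,y_cm``
* geometry — JSON with chamber vertex lists, entrance, arena and door
* peak table — CSV with header
  ``experiment_id,chamber_id,compound_id,retention_min,area``

Coordinates are continuous centimetres in a nest-local frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import FormatError, GeometryError

__all__ = [
    "NestGeometry",
    "TrackTable",
    "PeakTable",
    "read_tracks",
    "write_tracks",
    "read_geometry",
    "write_geometry",
    "read_peak_table",
    "write_peak_table",
]

TRACK_COLUMNS = ["time_s", "ant_id", "x_cm", "y_cm"]
PEAK_COLUMNS = ["experiment_id", "chamber_id", "compound_id", "retention_min", "area"]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NestGeometry:
    """Spatial reference for occupancy analysis.

    chambers: ordered (chamber_id, vertices) pairs, vertices in cm;
    entrance / door: 2-D points in cm; arena: polygon vertices in cm.
    Chamber polygons must be simple and pairwise non-overlapping (shared
    edges are allowed, positive-area intersections are not).
    """

    chambers: tuple
    entrance: tuple
    arena: tuple
    door: tuple

    def __post_init__(self) -> None:
        if len(self.chambers) < 1:
            raise GeometryError("geometry needs at least one chamber")
        polys = {}
        for cid, verts in self.chambers:
            if len(verts) < 3:
                raise GeometryError(f"chamber {cid!r} has fewer than 3 vertices")
            poly = Polygon(verts)
            if not poly.is_valid or poly.area <= 0:
                raise GeometryError(f"chamber {cid!r} polygon is not simple")
            polys[cid] = poly
        ids = list(polys)
        if len(set(ids)) != len(ids):
            raise GeometryError("duplicate chamber ids")
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                inter = polys[a].intersection(polys[b])
                if inter.area > 1e-9:
                    raise GeometryError(f"chambers overlap: ({a!r}, {b!r})")
        if len(self.arena) < 3:
            raise GeometryError("arena polygon needs at least 3 vertices")
        arena_poly = Polygon(self.arena)
        if not arena_poly.is_valid or arena_poly.area <= 0:
            raise GeometryError("arena polygon is not simple")

    @property
    def chamber_ids(self) -> list:
        return [cid for cid, _ in self.chambers]

    def chamber_polygons(self) -> Mapping[str, Polygon]:
        return {cid: Polygon(verts) for cid, verts in self.chambers}

    def arena_polygon(self) -> Polygon:
        return Polygon(self.arena)


@dataclass
class TrackTable:
    """Per-frame ant positions: columns time_s, ant_id, x_cm, y_cm."""

    frame: pd.DataFrame
    sampling_rate: float

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"track table missing column(s) {missing}")
        f = self.frame
        if not np.isfinite(f[["time_s", "x_cm", "y_cm"]].to_numpy(float)).all():
            raise FormatError("track table contains non-finite values")
        for ant, grp in f.groupby("ant_id", sort=False):
            t = grp["time_s"].to_numpy(float)
            if np.any(np.diff(t) < 0):
                raise FormatError(f"times decrease for ant {ant!r}")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TrackTable)
            and np.isclose(self.sampling_rate, other.sampling_rate)
            and self.frame.reset_index(drop=True).equals(other.frame.reset_index(drop=True))
        )


@dataclass
class PeakTable:
    """Integrated GC peaks, one row per (experiment, chamber, compound)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEAK_COLUMNS if c not in self.frame.columns]
        if missing:
            raise FormatError(f"peak table missing column(s) {missing}")
        f = self.frame
        bad = f.index[f["area"].to_numpy(float) < 0]
        if len(bad):
            raise FormatError(f"negative area at row(s) {list(bad)}")
        key = ["experiment_id", "chamber_id", "compound_id"]
        dup = f.duplicated(subset=key)
        if dup.any():
            raise FormatError(
                f"duplicate (experiment, chamber, compound) at row(s) {list(f.index[dup])}"
            )

    def __eq__(self, other) -> bool:
        return isinstance(other, PeakTable) and self.frame.reset_index(drop=True).equals(
            other.frame.reset_index(drop=True)
        )


# ---------------------------------------------------------------------------
# Tracking tables
# ---------------------------------------------------------------------------


def read_tracks(path) -> TrackTable:
    """Read a tracking CSV; sampling rate is the reciprocal median frame gap."""
    path = Path(path)
    raw = pd.read_csv(path, dtype={"ant_id": str}, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    for col in ("time_s", "x_cm", "y_cm"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        if len(bad):
            raise FormatError(f"{path.name}: non-numeric {col!r} at row(s) {list(bad)}")
        if coerced.isna().any():
            raise FormatError(
                f"{path.name}: missing {col!r} at row(s) {list(raw.index[coerced.isna()])}"
            )
        raw[col] = coerced.astype(float)
    gaps = (
        raw.sort_values(["ant_id", "time_s"]).groupby("ant_id")["time_s"].diff().dropna()
    )
    gaps = gaps[gaps > 0]
    rate = float(1.0 / gaps.median()) if len(gaps) else float("nan")
    return TrackTable(frame=raw[TRACK_COLUMNS], sampling_rate=rate)


def write_tracks(table: TrackTable, path) -> None:
    table.frame[TRACK_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Nest geometry
# ---------------------------------------------------------------------------


def read_geometry(path) -> NestGeometry:
    """Read a JSON geometry config and validate it against the invariants."""
    path = Path(path)
    try:
        cfg = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path.name}: not valid JSON ({exc})") from exc
    for key in ("chambers", "entrance", "arena", "door"):
        if key not in cfg:
            raise FormatError(f"{path.name}: missing key {key!r}")
    chambers = tuple(
        (str(ch["id"]), tuple(tuple(map(float, v)) for v in ch["vertices"]))
        for ch in cfg["chambers"]
    )
    return NestGeometry(
        chambers=chambers,
        entrance=tuple(map(float, cfg["entrance"])),
        arena=tuple(tuple(map(float, v)) for v in cfg["arena"]),
        door=tuple(map(float, cfg["door"])),
    )


def write_geometry(geometry: NestGeometry, path) -> None:
    cfg = {
        "chambers": [
            {"id": cid, "vertices": [list(v) for v in verts]}
            for cid, verts in geometry.chambers
        ],
        "entrance": list(geometry.entrance),
        "arena": [list(v) for v in geometry.arena],
        "door": list(geometry.door),
    }
    Path(path).write_text(json.dumps(cfg, indent=1))


def square_nest(
    side: float = 15.0,
    chamber_ids: Sequence[str] = ("1", "2", "3", "Q"),
    arena_margin: float = 10.0,
) -> NestGeometry:
    """Symmetric four-chamber nest: a square split into quadrants, entrance at
    the centre, surrounded by a square arena ring (modelled as the bounding
    frame polygon; chamber interiors take precedence in region assignment)."""
    h = side / 2.0
    quads = [
        ((0, 0), (h, 0), (h, h), (0, h)),
        ((h, 0), (side, 0), (side, h), (h, h)),
        ((h, h), (side, h), (side, side), (h, side)),
        ((0, h), (h, h), (h, side), (0, side)),
    ]
    m = arena_margin
    arena = ((-m, -m), (side + m, -m), (side + m, side + m), (-m, side + m))
    return NestGeometry(
        chambers=tuple(zip([str(c) for c in chamber_ids], [tuple(q) for q in quads])),
        entrance=(h, h),
        arena=arena,
        door=(h, h),
    )


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------


def read_peak_table(path) -> PeakTable:
    path = Path(path)
    raw = pd.read_csv(
        path,
        dtype={"experiment_id": str, "chamber_id": str, "compound_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in PEAK_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    for col in ("retention_min", "area"):
        coerced = pd.to_numeric(raw[col], errors="coerce")
        if coerced.isna().any():
            raise FormatError(
                f"{path.name}: bad {col!r} at row(s) {list(raw.index[coerced.isna()])}"
            )
        raw[col] = coerced.astype(float)
    return PeakTable(frame=raw[PEAK_COLUMNS])


def write_peak_table(table: PeakTable, path) -> None:
    table.frame[PEAK_COLUMNS].to_csv(path, index=False)
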