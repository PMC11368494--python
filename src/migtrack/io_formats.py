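"""Reading and writing every external representation the pipeline touches.

Tracks come in as Movebank-style CSV (configurable column names), regions as
GeoJSON FeatureCollections, segmentations go out as CSV, and utilization
distributions as ESRI ASCII grids with a sidecar ``.prj`` carrying the
projection string. All timestamps are normalized to UTC at read time; input
offsets are honored if present, otherwise UTC is assumed (and logged).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape
from shapely.validation import make_valid

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file (missing column, bad row, invalid value)."""


class EmptyTrackError(ValueError):
    """An operation left a track with no fixes."""


#: Default Movebank export column names.
DEFAULT_COLUMNS: dict[str, str] = {
    "individual_id": "individual-local-identifier",
    "timestamp": "timestamp",
    "lon": "location-long",
    "lat": "location-lat",
    "hdop": "gps:hdop",
    "ground_speed": "ground-speed",
}


@dataclass(frozen=True)
class GPSFix:
    """A single GPS location. hdop/ground_speed may be NaN when unreported."""

    individual_id: str
    timestamp: pd.Timestamp
    lon: float
    lat: float
    hdop: float = float("nan")
    ground_speed: float = float("nan")


@dataclass
class GPSTrack:
    """Ordered, quality-controllable fixes for one individual-season.

    Column arrays are aligned; ``timestamps`` are tz-aware UTC and strictly
    increasing. ``hdop``/``speed`` hold NaN where the device reported nothing.
    """

    individual_id: str
    timestamps: pd.DatetimeIndex
    lon: np.ndarray
    lat: np.ndarray
    hdop: np.ndarray = None
    speed: np.ndarray = None
    nominal_interval_min: float = 30.0

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        n = len(self.timestamps)
        if self.hdop is None:
            self.hdop = np.full(n, np.nan)
        if self.speed is None:
            self.speed = np.full(n, np.nan)
        self.hdop = np.asarray(self.hdop, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if not (len(self.lon) == len(self.lat) == len(self.hdop) == len(self.speed) == n):
            raise ValueError("track arrays have mismatched lengths")
        if n > 1 and not (np.diff(self.timestamps.asi8) > 0).all():
            raise ValueError(f"track {self.individual_id}: timestamps not strictly increasing")
        self._validate_values()

    def _validate_values(self):
        if len(self.lon) and (np.abs(self.lon) > 180).any():
            raise ValueError(f"track {self.individual_id}: longitude out of [-180, 180]")
        if len(self.lat) and (np.abs(self.lat) > 90).any():
            raise ValueError(f"track {self.individual_id}: latitude out of [-90, 90]")
        with np.errstate(invalid="ignore"):
            if len(self.hdop) and (self.hdop < 0).any():
                raise ValueError(f"track {self.individual_id}: negative HDOP")
            if len(self.speed) and (self.speed < 0).any():
                raise ValueError(f"track {self.individual_id}: negative ground speed")

    def __len__(self) -> int:
        return len(self.timestamps)

    def fix(self, i: int) -> GPSFix:
        return GPSFix(self.individual_id, self.timestamps[i], self.lon[i],
                      self.lat[i], self.hdop[i], self.speed[i])

    def subset(self, mask_or_index) -> "GPSTrack":
        """New track with the selected fixes (order preserved)."""
        idx = np.asarray(mask_or_index)
        return GPSTrack(self.individual_id, self.timestamps[idx], self.lon[idx],
                        self.lat[idx], self.hdop[idx], self.speed[idx],
                        self.nominal_interval_min)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "individual_id": self.individual_id,
            "timestamp": self.timestamps,
            "lon": self.lon, "lat": self.lat,
            "hdop": self.hdop, "speed": self.speed,
        })


@dataclass
class RegionSet:
    """Named WGS84 polygons (multi-part allowed) with unique labels."""

    polygons: dict[str, shapely.Geometry] = field(default_factory=dict)

    def __post_init__(self):
        for label, geom in self.polygons.items():
            if not geom.is_valid:
                self.polygons[label] = make_valid(geom)

    @property
    def labels(self) -> list[str]:
        return list(self.polygons)

    def locate(self, lon: float, lat: float, default: str = "Other") -> str:
        """Label of the first region containing the point, else ``default``."""
        pt = shapely.points(lon, lat)
        for label, geom in self.polygons.items():
            if geom.covers(pt):
                return label
        return default

    def locate_many(self, lons, lats, default: str = "Other") -> np.ndarray:
        pts = shapely.points(np.asarray(lons, float), np.asarray(lats, float))
        out = np.full(len(pts), default, dtype=object)
        for label, geom in self.polygons.items():
            hit = shapely.covers(geom, pts) & (out == default)
            out[hit] = label
        return out


def read_tracks(path, column_map: Mapping[str, str] | None = None,
                nominal_interval_min: float = 30.0) -> list[GPSTrack]:
    """Load one ``GPSTrack`` per individual from a CSV of fixes.

    Fixes are sorted by time within each individual regardless of file order;
    duplicate timestamps within an individual keep the first occurrence (count
    logged). Rows with out-of-range coordinates or unparseable timestamps
    raise :class:`FormatError` naming the offending line.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    for key in ("individual_id", "timestamp", "lon", "lat"):
        if cols[key] not in df.columns:
            raise FormatError(f"missing mandatory column '{cols[key]}' (for {key}) in {path}")

    ts = pd.to_datetime(df[cols["timestamp"]], utc=True, errors="coerce", format="mixed")
    if ts.isna().any():
        line = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 2  # +1 header, +1 1-based
        raise FormatError(f"unparseable timestamp at line {line} of {path}")
    lon = pd.to_numeric(df[cols["lon"]], errors="coerce").to_numpy()
    lat = pd.to_numeric(df[cols["lat"]], errors="coerce").to_numpy()
    bad = ~np.isfinite(lon) | ~np.isfinite(lat) | (np.abs(lon) > 180) | (np.abs(lat) > 90)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2
        raise FormatError(f"invalid coordinates at line {line} of {path}")

    work = pd.DataFrame({
        "id": df[cols["individual_id"]].astype(str),
        "t": ts, "lon": lon, "lat": lat,
        "hdop": pd.to_numeric(df[cols["hdop"]], errors="coerce")
                if cols["hdop"] in df.columns else np.nan,
        "speed": pd.to_numeric(df[cols["ground_speed"]], errors="coerce")
                 if cols["ground_speed"] in df.columns else np.nan,
    })

    tracks = []
    for ind, grp in work.groupby("id", sort=True):
        grp = grp.sort_values("t", kind="stable")
        dup = grp["t"].duplicated()
        if dup.any():
            logger.info("track %s: dropped %d duplicate-timestamp fixes", ind, int(dup.sum()))
            grp = grp[~dup]
        tracks.append(GPSTrack(
            str(ind), pd.DatetimeIndex(grp["t"]), grp["lon"].to_numpy(),
            grp["lat"].to_numpy(), grp["hdop"].to_numpy(), grp["speed"].to_numpy(),
            nominal_interval_min))
    return tracks


def write_tracks(tracks: Sequence[GPSTrack], path,
                 column_map: Mapping[str, str] | None = None) -> None:
    """Write tracks back to CSV with the given (default Movebank) column names."""
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    frames = []
    for tr in tracks:
        f = tr.to_frame()
        f["timestamp"] = f["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
        frames.append(f.rename(columns={
            "individual_id": cols["individual_id"], "timestamp": cols["timestamp"],
            "lon": cols["lon"], "lat": cols["lat"], "hdop": cols["hdop"],
            "speed": cols["ground_speed"]}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_regions(path, label_property: str = "name") -> RegionSet:
    """Load a RegionSet from a GeoJSON FeatureCollection."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    polys: dict[str, shapely.Geometry] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if label_property not in props:
            raise FormatError(f"{path}: feature missing '{label_property}' property")
        label = str(props[label_property])
        if label in polys:
            raise FormatError(f"{path}: duplicate region label '{label}'")
        polys[label] = shape(feat["geometry"])
    return RegionSet(polys)


# --- segment tables -------------------------------------------------------

def write_segments(segmented, path) -> None:
    """One CSV row per step: state, role, segment id, cumulative km.

    Round-trips losslessly through :func:`read_segments`. An empty
    segmentation yields a header-only file.
    """
    rows = segmented.to_frame()
    rows.insert(0, "individual_id", segmented.individual_id)
    rows.to_csv(path, index=False, float_format="%.10g")


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path)


# --- UD rasters -----------------------------------------------------------

def write_ud(grid, path) -> None:
    """Write a UD grid as an ESRI ASCII raster plus a ``.prj`` sidecar.

    Values are written with 10 significant digits; georeferencing records the
    grid origin (lower-left corner), cell size and projection string.
    """
    vals = np.asarray(grid.values, dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValueError("UD grid contains non-finite or negative cells")
    path = Path(path)
    ny, nx = vals.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {grid.x0:.10g}\n")
        fh.write(f"yllcorner {grid.y0:.10g}\n")
        fh.write(f"cellsize {grid.cell_size_km:.10g}\n")
        fh.write("NODATA_value -9999\n")
        for row in vals[::-1]:  # ASCII grid runs top row first
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    path.with_suffix(".prj").write_text(grid.projection.proj_string + "\n")


def read_ud(path):
    """Read an ESRI ASCII raster written by :func:`write_ud`."""
    from .dbbmm import UDGrid
    from .projection import AlbersEqualArea

    path = Path(path)
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner", "yllcorner",
                                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    vals = np.array(rows[::-1], dtype=float)
    if vals.shape != (int(header["nrows"]), int(header["ncols"])):
        raise FormatError(f"{path}: grid shape does not match header")
    return UDGrid(x0=header["xllcorner"], y0=header["yllcorner"],
                  cell_size_km=header["cellsize"], values=vals,
                  projection=AlbersEqualArea())
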