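"""Reading, writing and validation of tracking data, masks and weather.

All coordinates are WGS84 decimal degrees and all timestamps are UTC.
Distances are great-circle (haversine) with the IUGG mean Earth radius;
over the <100 km ranges of a breeding gull the error against an ellipsoid
is negligible, so no projection is used anywhere in the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

log = logging.getLogger("gullforage")

EARTH_RADIUS_M = 6_371_008.8  # IUGG mean radius

FIX_COLUMNS = ["individual_id", "timestamp_utc", "lon", "lat", "speed_ms"]
REQUIRED_FIX_COLUMNS = FIX_COLUMNS[:4]
WEATHER_COLUMNS = ["timestamp_utc", "cloud", "temp", "ppt_rate", "wind_ew", "wind_ns"]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class RowError(ValueError):
    """One or more data rows failed validation; carries (line, reason) pairs."""

    def __init__(self, message: str, rows: list[tuple[int, str]]):
        super().__init__(message)
        self.rows = rows


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray | float:
    """Great-circle distance in metres between WGS84 points (vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def destination_point(lon, lat, bearing_deg, distance_m):
    """Point reached from (lon, lat) on the given initial bearing (vectorised)."""
    lon1 = np.radians(np.asarray(lon, dtype=float))
    lat1 = np.radians(np.asarray(lat, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(brg))
    lon2 = lon1 + np.arctan2(np.sin(brg) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    return np.degrees(lon2), np.degrees(lat2)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Track:
    """Time-ordered GPS fixes of a single individual.

    ``fixes`` is a DataFrame with columns ``timestamp_utc`` (tz-aware UTC),
    ``lon``, ``lat`` and ``speed_ms`` (NaN where the logger reported none),
    sorted strictly increasing in time.
    """

    individual_id: str
    fixes: pd.DataFrame

    def __post_init__(self):
        ts = self.fixes["timestamp_utc"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise ValueError(f"track {self.individual_id}: timestamps not sorted")

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class WeatherSeries:
    """Regular (or at least strictly ordered) weather series at the colony.

    Columns: cloud (% of sky, 0-100), temp (deg C), ppt_rate (kg m-2 s-1 or any
    fixed rate unit, >= 0), wind_ew (m/s, east positive), wind_ns (m/s, north
    positive). Indexed by tz-aware UTC timestamps.
    """

    data: pd.DataFrame

    def __post_init__(self):
        idx = self.data.index
        if len(idx) > 1 and not idx.is_monotonic_increasing:
            raise ValueError("weather timestamps not strictly increasing")
        if self.data[["cloud", "temp", "ppt_rate", "wind_ew", "wind_ns"]].isna().any().any():
            raise ValueError("weather series contains missing values")

    @property
    def start(self) -> pd.Timestamp:
        return self.data.index[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.data.index[-1]


@dataclass
class LandMask:
    """Set of land polygons; a point on a polygon boundary counts as land."""

    polygons: list[BaseGeometry] = field(default_factory=list)

    def __post_init__(self):
        for i, g in enumerate(self.polygons):
            if not g.is_valid:
                raise FormatError(f"mask polygon {i} is invalid (self-intersecting?)")

    def contains(self, lon, lat) -> np.ndarray:
        """Boundary-inclusive land membership for arrays of coordinates."""
        from shapely import points as _mkpoints  # vectorised constructor
        pts = _mkpoints(np.asarray(lon, dtype=float), np.asarray(lat, dtype=float))
        out = np.zeros(np.shape(pts), dtype=bool)
        for g in self.polygons:
            # covers == contains + boundary
            import shapely
            out |= shapely.covers(g, pts)
        if out.ndim == 0:
            return bool(out)
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fixes(path) -> list[Track]:
    """Read a GPS fix CSV into per-individual, time-sorted :class:`Track`s.

    The file must carry columns ``individual_id, timestamp_utc, lon, lat``
    with optional ``speed_ms``. Rows with unparseable timestamps or
    out-of-range coordinates are rejected with their line numbers; duplicate
    timestamps within an individual are collapsed to the first occurrence
    with a warning. No row is ever silently dropped.
    """
    raw = pd.read_csv(path, dtype={"individual_id": str},
                      float_precision="round_trip")
    missing = [c for c in REQUIRED_FIX_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"fix file missing required column(s): {', '.join(missing)}")
    if "speed_ms" not in raw.columns:
        raw["speed_ms"] = np.nan

    # line numbers: header is line 1
    lines = np.arange(2, len(raw) + 2)
    bad: list[tuple[int, str]] = []

    ts = pd.to_datetime(raw["timestamp_utc"], utc=True, errors="coerce")
    for ln in lines[ts.isna().to_numpy()]:
        bad.append((int(ln), "unparseable timestamp"))
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    speed = pd.to_numeric(raw["speed_ms"], errors="coerce")
    coord_bad = (lon.isna() | lat.isna() | (lon < -180) | (lon > 180)
                 | (lat < -90) | (lat > 90))
    for ln in lines[(coord_bad & ts.notna()).to_numpy()]:
        bad.append((int(ln), "invalid coordinate"))
    speed_bad = speed.notna() & (speed < 0)
    for ln in lines[(speed_bad & ts.notna() & ~coord_bad).to_numpy()]:
        bad.append((int(ln), "negative speed"))

    if bad:
        raise RowError(
            f"{len(bad)} invalid row(s), first at line {bad[0][0]} ({bad[0][1]})",
            sorted(bad),
        )

    df = pd.DataFrame({
        "individual_id": raw["individual_id"],
        "timestamp_utc": ts,
        "lon": lon, "lat": lat, "speed_ms": speed,
    })
    tracks = []
    for ind, g in df.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp_utc", kind="mergesort")
        dup = g["timestamp_utc"].duplicated()
        if dup.any():
            log.warning("individual %s: %d duplicate timestamp(s) collapsed",
                        ind, int(dup.sum()))
            g = g[~dup]
        tracks.append(Track(str(ind), g.drop(columns="individual_id")
                            .reset_index(drop=True)))
    return tracks


def write_fixes(tracks: list[Track], path) -> None:
    frames = []
    for t in tracks:
        f = t.fixes.copy()
        f.insert(0, "individual_id", t.individual_id)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=FIX_COLUMNS)
    out.to_csv(path, index=False)


def derive_speed(track: Track) -> Track:
    """Fill missing speeds from consecutive-fix haversine displacement.

    The speed between fixes i-1 and i is assigned to fix i; a missing speed on
    the first fix becomes 0. Instrument-reported speeds are kept where present
    (less quantisation error than a 300 s displacement estimate). A track
    with no missing speed is returned unchanged.
    """
    f = track.fixes
    if not f["speed_ms"].isna().any():
        return track
    f = f.copy()
    if len(f) >= 2:
        d = haversine_m(f["lon"].to_numpy()[:-1], f["lat"].to_numpy()[:-1],
                        f["lon"].to_numpy()[1:], f["lat"].to_numpy()[1:])
        dt = np.diff(f["timestamp_utc"].astype("int64").to_numpy()) / 1e9
        derived = np.concatenate([[0.0], np.asarray(d) / dt])
    else:
        derived = np.zeros(len(f))
    f["speed_ms"] = f["speed_ms"].fillna(pd.Series(derived, index=f.index))
    return Track(track.individual_id, f)


def read_weather(path) -> WeatherSeries:
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WEATHER_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"weather file missing column(s): {', '.join(missing)}")
    ts = pd.to_datetime(raw["timestamp_utc"], utc=True, errors="coerce")
    if ts.isna().any():
        raise FormatError("weather file has unparseable timestamps")
    df = raw[["cloud", "temp", "ppt_rate", "wind_ew", "wind_ns"]].astype(float)
    idx = pd.DatetimeIndex(ts)
    idx.name = None
    df.index = idx
    return WeatherSeries(df)


def write_weather(series: WeatherSeries, path) -> None:
    out = series.data.copy()
    out.insert(0, "timestamp_utc", out.index)
    out.to_csv(path, index=False)


def read_mask(path) -> LandMask:
    """Read a GeoJSON FeatureCollection (or bare geometry) of land polygons."""
    with open(path) as fh:
        gj = json.load(fh)
    geoms: list[BaseGeometry] = []
    try:
        if gj.get("type") == "FeatureCollection":
            for feat in gj["features"]:
                geoms.append(shape(feat["geometry"]))
        elif gj.get("type") == "Feature":
            geoms.append(shape(gj["geometry"]))
        else:
            geoms.append(shape(gj))
    except Exception as exc:  # malformed coordinates / unknown type
        raise FormatError(f"invalid GeoJSON geometry: {exc}") from exc
    return LandMask(geoms)


def write_mask(mask: LandMask, path) -> None:
    gj = {"type": "FeatureCollection",
          "features": [{"type": "Feature", "properties": {},
                        "geometry": mapping(g)} for g in mask.polygons]}
    with open(path, "w") as fh:
        json.dump(gj, fh)


def write_trip_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_trip_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual_id": str, "trip_id": str},
                     float_precision="round_trip")
    for col in ("departure_time", "return_time"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], utc=True)
    return df


def write_fit_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)


def read_fit_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
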