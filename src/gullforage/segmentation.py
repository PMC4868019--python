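"""Cutting tracks into central-place foraging trips and filtering them.

A trip is one excursion beyond a 500 m radius of the individual's nest:
it opens at the first fix farther than the radius that follows a fix within
it, and closes symmetrically on return. Departure and return instants are
taken as the midpoint between the bracketing inside/outside fixes, which is
unbiased under regular sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Track, haversine_m


@dataclass
class Trip:
    """One foraging excursion with its fixes and derived metrics."""

    individual_id: str
    trip_id: str
    departure_time: pd.Timestamp
    return_time: pd.Timestamp
    fixes: pd.DataFrame  # timestamp_utc, lon, lat, speed_ms, interpolated
    complete: bool

    @property
    def duration_h(self) -> float:
        return (self.return_time - self.departure_time).total_seconds() / 3600.0

    @property
    def year(self) -> int:
        return int(self.departure_time.year)

    def max_distance_km(self, colony: tuple[float, float]) -> float:
        if len(self.fixes) == 0:
            return 0.0
        d = haversine_m(self.fixes["lon"].to_numpy(), self.fixes["lat"].to_numpy(),
                        colony[0], colony[1])
        return float(np.max(d)) / 1000.0


@dataclass
class FilterConfig:
    """Retention rules for analyzable foraging trips.

    The thresholds are artifact conventions surfaced here so every run
    states them; the analysis window defaults to the May 20 - Jul 21 focal
    period and can be widened to include pre-laying (Apr 30).
    """

    min_duration_h: float = 0.5
    min_distance_km: float = 3.0
    min_fixes: int = 5
    max_gap_frac: float = 0.5
    require_complete: bool = True
    window_start: tuple[int, int] = (5, 20)   # (month, day), inclusive
    window_end: tuple[int, int] = (7, 21)


def segment_trips(track: Track, nest: tuple[float, float],
                  radius_m: float = 500.0) -> list[Trip]:
    """Segment one individual's track into trips around its nest.

    Fixes within the radius belong to no trip. A trip still open when the
    track ends — or already open when it starts — is flagged incomplete
    (its departure or return instant is unbracketed).
    """
    f = track.fixes
    if len(f) == 0:
        return []
    d = np.asarray(haversine_m(f["lon"].to_numpy(), f["lat"].to_numpy(),
                               nest[0], nest[1]), dtype=float).reshape(-1)
    outside = d > radius_m
    ts = f["timestamp_utc"].reset_index(drop=True)

    trips: list[Trip] = []
    i, n = 0, len(f)
    counter = 0
    while i < n:
        if not outside[i]:
            i += 1
            continue
        j = i
        while j < n and outside[j]:
            j += 1
        # fixes i..j-1 are one excursion
        if i > 0:
            dep = ts[i - 1] + (ts[i] - ts[i - 1]) / 2
            start_bracketed = True
        else:
            dep = ts[i]
            start_bracketed = False
        if j < n:
            ret = ts[j - 1] + (ts[j] - ts[j - 1]) / 2
            end_bracketed = True
        else:
            ret = ts[n - 1]
            end_bracketed = False
        sub = f.iloc[i:j].copy().reset_index(drop=True)
        if "interpolated" not in sub.columns:
            sub["interpolated"] = False
        trips.append(Trip(
            individual_id=track.individual_id,
            trip_id=f"{track.individual_id}_{counter:04d}",
            departure_time=dep, return_time=ret, fixes=sub,
            complete=start_bracketed and end_bracketed,
        ))
        counter += 1
        i = j
    return trips


def interpolate_trip(trip: Trip, step_s: float = 300.0,
                     max_gap_s: float = 2700.0) -> Trip:
    """Resample a trip's positions onto a regular time grid.

    Positions (and speeds) are linearly interpolated in time at multiples of
    ``step_s`` across the raw fix span, so each grid point represents an
    equal slice of trip time. Grid points falling inside a raw-data gap
    longer than ``max_gap_s`` (default 45 min) are omitted rather than
    bridged. Grid points coinciding with a raw fix reproduce it exactly and
    are not flagged as interpolated.
    """
    f = trip.fixes
    if len(f) < 2:
        return trip
    t = f["timestamp_utc"].astype("int64").to_numpy() / 1e9
    t0, t1 = t[0], t[-1]
    grid = t0 + step_s * np.arange(0, np.floor((t1 - t0) / step_s) + 1)
    # locate bracketing raw intervals; drop points inside long gaps
    idx = np.searchsorted(t, grid, side="right") - 1
    idx = np.clip(idx, 0, len(t) - 2)
    gap = t[idx + 1] - t[idx]
    on_raw = (np.abs(grid[:, None] - t[None, :]) < 0.5).any(axis=1)
    keep = on_raw | (gap <= max_gap_s)
    grid = grid[keep]
    on_raw = on_raw[keep]

    lon = np.interp(grid, t, f["lon"].to_numpy())
    lat = np.interp(grid, t, f["lat"].to_numpy())
    spd = np.interp(grid, t, f["speed_ms"].to_numpy())
    out = pd.DataFrame({
        "timestamp_utc": pd.to_datetime(grid * 1e9, utc=True),
        "lon": lon, "lat": lat, "speed_ms": spd,
        "interpolated": ~on_raw,
    })
    return Trip(trip.individual_id, trip.trip_id, trip.departure_time,
                trip.return_time, out, trip.complete)


def _largest_gap_s(trip: Trip) -> float:
    t = trip.fixes["timestamp_utc"].astype("int64").to_numpy() / 1e9
    if len(t) < 2:
        return 0.0
    return float(np.max(np.diff(t)))


def filter_trips(trips: list[Trip], rules: FilterConfig,
                 colony: tuple[float, float]) -> tuple[list[Trip], pd.DataFrame]:
    """Retain analyzable trips; log every exclusion with its (first) reason."""
    kept: list[Trip] = []
    excluded: list[dict] = []

    def _reason(trip: Trip) -> str | None:
        if rules.require_complete and not trip.complete:
            return "incomplete"
        if trip.duration_h < rules.min_duration_h:
            return "min_duration"
        if trip.max_distance_km(colony) < rules.min_distance_km:
            return "min_distance"
        if len(trip.fixes) < rules.min_fixes:
            return "min_fixes"
        dur_s = trip.duration_h * 3600.0
        if dur_s > 0 and _largest_gap_s(trip) > rules.max_gap_frac * dur_s:
            return "max_gap"
        md = (trip.departure_time.month, trip.departure_time.day)
        if not (rules.window_start <= md <= rules.window_end):
            return "window"
        return None

    for trip in trips:
        r = _reason(trip)
        if r is None:
            kept.append(trip)
        else:
            excluded.append({"trip_id": trip.trip_id,
                             "individual_id": trip.individual_id,
                             "departure_time": trip.departure_time,
                             "reason": r})
    log = pd.DataFrame(excluded, columns=["trip_id", "individual_id",
                                          "departure_time", "reason"])
    return kept, log
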