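"""Foraging-point extraction, land/sea assignment and trip classification.

Likely foraging locations are the interpolated fixes travelling between the
two speed thresholds and at least 3 km from the colony; each is land or sea
by boundary-inclusive point-in-polygon membership against the land mask.
The per-trip proportion of foraging points on land (p_land) is the analysis
response; for illustration trips are classed sea (<5 % on land), mixed
(5-95 %) or land (>95 %), with exact 5 %/95 % resolving to mixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LandMask, haversine_m
from .segmentation import Trip

V_LOW_DEFAULT = 0.0    # m/s; lower foraging-speed threshold
V_HIGH_DEFAULT = 4.0   # m/s; above this a gull is in flapping flight
MIN_DIST_KM_DEFAULT = 3.0


class MissingSpeedError(ValueError):
    """Fixes carry no speeds; run derive_speed on the track first."""


@dataclass
class TripHabitat:
    trip_id: str
    n_forage_points: int
    n_land: int

    @property
    def p_land(self) -> float | None:
        if self.n_forage_points == 0:
            return None
        return self.n_land / self.n_forage_points

    @property
    def trip_class(self) -> str:
        return classify_trip(self.p_land)


def extract_foraging_points(trip: Trip, colony: tuple[float, float],
                            v_low: float = V_LOW_DEFAULT,
                            v_high: float = V_HIGH_DEFAULT,
                            min_dist_km: float = MIN_DIST_KM_DEFAULT,
                            ) -> pd.DataFrame:
    """Fixes with v_low <= speed <= v_high and >= min_dist_km from colony."""
    f = trip.fixes
    if f["speed_ms"].isna().any():
        raise MissingSpeedError(
            f"trip {trip.trip_id}: missing speeds; derive_speed first")
    if len(f) == 0:
        return f.assign(trip_id=pd.Series(dtype=str))
    d_km = np.asarray(haversine_m(f["lon"].to_numpy(), f["lat"].to_numpy(),
                                  colony[0], colony[1])).reshape(-1) / 1000.0
    spd = f["speed_ms"].to_numpy()
    sel = (spd >= v_low) & (spd <= v_high) & (d_km >= min_dist_km)
    out = f.loc[sel, ["timestamp_utc", "lon", "lat", "speed_ms"]].copy()
    out.insert(0, "trip_id", trip.trip_id)
    return out.reset_index(drop=True)


def assign_habitat(points: pd.DataFrame, mask: LandMask) -> pd.DataFrame:
    """Label each foraging point land/sea; never changes the point count."""
    out = points.copy()
    if len(out) == 0:
        out["habitat"] = pd.Series(dtype=str)
        return out
    on_land = mask.contains(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["habitat"] = np.where(on_land, "land", "sea")
    return out


def summarize_trip(points: pd.DataFrame) -> TripHabitat:
    """Counts and p_land for one trip's labelled foraging points."""
    if len(points) == 0:
        raise ValueError("empty point table: pass trip_id via summarize_trips")
    ids = points["trip_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"points span multiple trips: {ids.tolist()}")
    n = len(points)
    n_land = int((points["habitat"] == "land").sum())
    return TripHabitat(str(ids[0]), n, n_land)


def classify_trip(p_land: float | None) -> str:
    """sea (<0.05), mixed (0.05-0.95 inclusive), land (>0.95), unclassified."""
    if p_land is None:
        return "unclassified"
    if not 0.0 <= p_land <= 1.0:
        raise ValueError(f"p_land outside [0, 1]: {p_land}")
    if p_land < 0.05:
        return "sea"
    if p_land > 0.95:
        return "land"
    return "mixed"


def build_trip_records(trips: list[Trip], colony: tuple[float, float],
                       mask: LandMask,
                       v_low: float = V_LOW_DEFAULT,
                       v_high: float = V_HIGH_DEFAULT,
                       min_dist_km: float = MIN_DIST_KM_DEFAULT,
                       ) -> pd.DataFrame:
    """One analysis row per trip: identifiers, metrics, counts, class.

    Trips with no foraging point get n_forage_points = 0, NaN p_land and the
    class "unclassified"; they stay in the table (and are excluded later by
    the binomial model, which needs a positive denominator).
    """
    rows = []
    for trip in trips:
        pts = extract_foraging_points(trip, colony, v_low, v_high, min_dist_km)
        pts = assign_habitat(pts, mask)
        n = len(pts)
        n_land = int((pts["habitat"] == "land").sum()) if n else 0
        p = n_land / n if n else None
        rows.append({
            "trip_id": trip.trip_id,
            "individual_id": trip.individual_id,
            "departure_time": trip.departure_time,
            "return_time": trip.return_time,
            "duration_h": trip.duration_h,
            "max_distance_km": trip.max_distance_km(colony),
            "n_forage_points": n,
            "n_land": n_land,
            "p_land": np.nan if p is None else p,
            "trip_class": classify_trip(p),
        })
    return pd.DataFrame(rows)
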