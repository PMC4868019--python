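"""Trip-level covariates: sunrise proximity, weather, breeding stage, sex.

Sunrise is computed with the NOAA solar-position equations (sun centre at
-0.833 deg altitude, i.e. refraction + solar radius), good to about two
minutes against published ephemerides at mid latitudes. Timestamps are UTC
throughout the package; the only local-time notion used here is the local
*solar* calendar day (UTC shifted by longitude/15 h) that decides which
day's sunrise a departure is compared against.
"""

from __future__ import annotations

import datetime as dt
import math

import numpy as np
import pandas as pd

from .io import WeatherSeries

LATENT_LOGISTIC_VAR = math.pi ** 2 / 3.0  # logit-link distribution variance

#: inclusive month-day windows of the colony-wide breeding stages
STAGE_WINDOWS = [
    ("pre-laying", (4, 30), (5, 19)),
    ("incubation", (5, 20), (6, 9)),
    ("early chick-rearing", (6, 10), (6, 30)),
    ("late chick-rearing", (7, 1), (7, 21)),
]

SEX_THRESHOLD_MM = 113.5  # head+bill discriminant: below female, above male


class OutOfWindowError(ValueError):
    """Departure date falls outside every breeding-stage window."""


class CoverageError(ValueError):
    """Weather series does not cover the requested summary window."""


class IndeterminateSexError(ValueError):
    """Head+bill length sits exactly on the discriminant threshold."""


# ---------------------------------------------------------------------------
# solar position
# ---------------------------------------------------------------------------

def _solar_params(jc: float) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians).

    ``jc`` is Julian centuries since J2000. NOAA's low-precision series.
    """
    gmls = math.radians((280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0)
    gmas = math.radians(357.52911 + jc * (35999.05029 - 0.0001537 * jc))
    eeo = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    seqc = (math.sin(gmas) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
            + math.sin(2 * gmas) * (0.019993 - 0.000101 * jc)
            + math.sin(3 * gmas) * 0.000289)
    stl = math.degrees(gmls) + seqc
    sal = stl - 0.00569 - 0.00478 * math.sin(math.radians(125.04 - 1934.136 * jc))
    moe = (23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813)))
                   / 60.0) / 60.0)
    oc = moe + 0.00256 * math.cos(math.radians(125.04 - 1934.136 * jc))
    decl = math.asin(math.sin(math.radians(oc)) * math.sin(math.radians(sal)))
    vary = math.tan(math.radians(oc / 2.0)) ** 2
    eot = 4.0 * math.degrees(
        vary * math.sin(2.0 * gmls)
        - 2.0 * eeo * math.sin(gmas)
        + 4.0 * eeo * vary * math.sin(gmas) * math.cos(2.0 * gmls)
        - 0.5 * vary * vary * math.sin(4.0 * gmls)
        - 1.25 * eeo * eeo * math.sin(2.0 * gmas))
    return eot, decl


def sunrise_time(lon: float, lat: float, date: dt.date) -> pd.Timestamp:
    """UTC sunrise instant at (lon, lat) on the given calendar date.

    Raises for |lat| >= 66 deg where polar day/night would make the hour
    angle undefined in midsummer.
    """
    if abs(lat) >= 66.0:
        raise ValueError(f"unsupported latitude {lat}: polar day/night possible")
    # Julian day at civil noon UTC of `date`
    ord_ = date.toordinal()
    jd = ord_ + 1721424.5 + 0.5
    jc = (jd - 2451545.0) / 36525.0
    eot, decl = _solar_params(jc)
    latr = math.radians(lat)
    cos_ha = (math.cos(math.radians(90.833)) / (math.cos(latr) * math.cos(decl))
              - math.tan(latr) * math.tan(decl))
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha = math.degrees(math.acos(cos_ha))
    solar_noon_min = 720.0 - 4.0 * lon - eot  # minutes after UTC midnight
    sunrise_min = solar_noon_min - 4.0 * ha
    base = pd.Timestamp(date.year, date.month, date.day, tz="UTC")
    return base + pd.to_timedelta(sunrise_min, unit="min")


def sunrise_proximity(t_since_sunrise_h: float | np.ndarray) -> float | np.ndarray:
    """cos(pi * t / 12) of signed hours since sunrise, wrapped to (-12, 12].

    1 at sunrise, 0 at +/-6 h, -1 at 12 h; even in its argument.
    """
    t = np.asarray(t_since_sunrise_h, dtype=float)
    t = t - 24.0 * np.ceil((t - 12.0) / 24.0)  # wrap into (-12, 12]
    out = np.cos(np.pi * t / 12.0)
    if out.ndim == 0:
        return float(out)
    return out


def time_since_sunrise(lon: float, lat: float, t_dep: pd.Timestamp) -> float:
    """Signed hours between ``t_dep`` and sunrise of its local solar day."""
    local = t_dep + pd.to_timedelta(lon / 15.0, unit="h")
    sr = sunrise_time(lon, lat, local.date())
    return (t_dep - sr).total_seconds() / 3600.0


# ---------------------------------------------------------------------------
# weather, stage, sex
# ---------------------------------------------------------------------------

def weather_summary(series: WeatherSeries, t_dep: pd.Timestamp) -> dict:
    """24 h pre-departure weather summary.

    Each variable is linearly interpolated in time to the four instants
    t_dep, t_dep-6 h, t_dep-12 h, t_dep-18 h; the mean of the four is
    reported, except precipitation rate where the sum is taken (cumulative
    rain over the preceding day).
    """
    t_dep = pd.Timestamp(t_dep)
    instants = [t_dep - pd.Timedelta(hours=h) for h in (18, 12, 6, 0)]
    if instants[0] < series.start or t_dep > series.end:
        raise CoverageError(
            f"weather series [{series.start} .. {series.end}] does not cover "
            f"[{instants[0]} .. {t_dep}]")
    t_ns = series.data.index.astype("int64").to_numpy()
    q_ns = np.array([t.value for t in instants], dtype="int64")
    out = {}
    for col in ("cloud", "temp", "ppt_rate", "wind_ew", "wind_ns"):
        vals = np.interp(q_ns, t_ns, series.data[col].to_numpy())
        out[col] = float(vals.sum() if col == "ppt_rate" else vals.mean())
    return {"cloud": out["cloud"], "temp": out["temp"], "ppt": out["ppt_rate"],
            "windEW": out["wind_ew"], "windNS": out["wind_ns"]}


def breeding_stage(date: dt.date) -> str:
    """Colony-wide stage for a departure date (inclusive calendar windows)."""
    md = (date.month, date.day)
    for name, lo, hi in STAGE_WINDOWS:
        if lo <= md <= hi:
            return name
    raise OutOfWindowError(f"{date} outside the Apr 30 - Jul 21 analysis window")


def sex_from_morphometrics(head_bill_mm: float) -> str:
    """Sex from head+bill length: < 113.5 mm female, > 113.5 mm male."""
    if not head_bill_mm > 0:
        raise ValueError(f"non-positive head+bill length: {head_bill_mm}")
    if head_bill_mm < SEX_THRESHOLD_MM:
        return "female"
    if head_bill_mm > SEX_THRESHOLD_MM:
        return "male"
    raise IndeterminateSexError(
        f"head+bill exactly {SEX_THRESHOLD_MM} mm: sex indeterminate")


def annotate_trips(records: pd.DataFrame, weather: WeatherSeries,
                   individuals: pd.DataFrame, colony: tuple[float, float],
                   ) -> pd.DataFrame:
    """Attach sunrise proximity, stage, year, sex and 24 h weather to records.

    ``records`` must carry individual_id and departure_time; ``individuals``
    maps individual_id to head_bill_mm. Trips departing outside the stage
    windows are dropped (they are excluded from analysis upstream anyway).
    """
    lon, lat = colony
    meta = individuals.set_index("individual_id")
    rows = []
    for _, r in records.iterrows():
        t_dep = pd.Timestamp(r["departure_time"])
        local = t_dep + pd.to_timedelta(lon / 15.0, unit="h")
        try:
            stage = breeding_stage(local.date())
        except OutOfWindowError:
            continue
        tss = time_since_sunrise(lon, lat, t_dep)
        w = weather_summary(weather, t_dep)
        out = dict(r)
        out.update(w)
        out["sunrise_prox"] = sunrise_proximity(tss)
        out["stage"] = stage
        out["year"] = int(local.year)
        out["sex"] = sex_from_morphometrics(
            float(meta.loc[str(r["individual_id"]), "head_bill_mm"]))
        rows.append(out)
    return pd.DataFrame(rows).reset_index(drop=True)
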