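"""Synthetic GPS tracks, weather and field observations for a gull colony.

The generator emulates the statistical structure a central-place foraging
analysis assumes: ~19 individuals over three breeding seasons producing
~1038 trips; a land/mixed/sea trip mixture; class-specific right-skewed
duration and range distributions (lognormals matched to printed medians and
interquartile ranges); pre-dawn departure peaks for terrestrial trips;
autocorrelated colony weather; and strong, consistent between-individual
differences in terrestrial propensity.

Generative model for habitat choice: each trip carries a latent land
propensity eta = b_i + beta'x + e where b_i is the individual's intercept
(Normal, sd ``individual_propensity_sd``), x holds sunrise proximity and
standardised cloud/temperature, and e is standard logistic — so the latent
within-individual variance is pi^2/3, matching the logit-link variance used
by the downstream repeatability estimate. Trip classes come from a
class-decision score b_i + beta'x + kappa*e (kappa < 1: birds choose where
to go more consistently than their point-level scatter implies),
thresholded at quantiles of the realised cohort so the configured mixture
is reproduced at cohort level. Within the mixed band the score maps
monotonically onto the trip's land fraction; land and sea trips sit at a
fixed depth inside their printed class bands (> 95 % / < 5 %), with the
depth self-calibrated so the cohort's aggregate land-rate spread reproduces
the configured between-individual variance. Every trip is rendered as an
out-commute, foraging bout(s) (slow fixes on land and/or at sea) and a
return commute, with ground-truth labels emitted in sidecar tables.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from shapely.geometry import Polygon

from .covariates import sunrise_time, sunrise_proximity, weather_summary
from .io import LandMask, Track, WeatherSeries, destination_point, haversine_m

M_PER_DEG_LAT = 111_320.0

#: (land, mixed, sea) shares of classified trips: 220, 93 and 711 of 1024
DEFAULT_MIXTURE = (220 / 1024, 93 / 1024, 711 / 1024)

#: individual-intercept sd giving latent repeatability 0.814
DEFAULT_PROPENSITY_SD = math.sqrt(0.814 / (1.0 - 0.814) * math.pi ** 2 / 3.0)

CLASSES = ("land", "mixed", "sea")


class ConfigurationError(ValueError):
    """A scenario field is invalid; the message names the field."""


class GenerationError(RuntimeError):
    """A trip could not be rendered inside the synthetic world."""


def _check_class_dict(name: str, d: dict) -> None:
    for c in CLASSES:
        if c not in d:
            raise ConfigurationError(f"{name} missing class {c!r}")


@dataclass
class Scenario:
    """Full generative configuration; defaults define the standard run S1.

    Durations and maximum distances are lognormal per class, parameterised
    by (median, (q25, q75)): mu = ln median, sigma = ln(q75/q25)/(2*0.6745).
    ``fixed_effects`` are logit-scale coefficients on sunrise proximity and
    standardised 24 h cloud and temperature.
    """

    seed: int = 0
    n_individuals: int = 19
    n_years: int = 3
    start_year: int = 2011
    colony: tuple[float, float] = (17.9667, 57.2833)  # lon, lat
    nest_jitter_m: float = 100.0
    sampling_interval_s: float = 300.0
    gap_rate: float = 0.02
    trips_per_individual_year: float = 1038.0 / (19 * 3)
    trip_class_mixture: tuple[float, float, float] = DEFAULT_MIXTURE
    duration_medians_h: dict = dc_field(default_factory=lambda: {
        "land": 6.2, "sea": 3.9, "mixed": 11.3})
    duration_iqrs_h: dict = dc_field(default_factory=lambda: {
        "land": (4.1, 9.8), "sea": (2.2, 6.8), "mixed": (8.1, 15.0)})
    maxdist_medians_km: dict = dc_field(default_factory=lambda: {
        "land": 20.8, "sea": 23.2, "mixed": 39.3})
    maxdist_iqrs_km: dict = dc_field(default_factory=lambda: {
        "land": (17.4, 22.7), "sea": (13.2, 41.1), "mixed": (22.6, 49.3)})
    individual_propensity_sd: float = DEFAULT_PROPENSITY_SD
    #: scale of the trip-level noise entering the *class decision* relative
    #: to the point-level logistic noise: birds choose where to go more
    #: consistently than the scatter of individual foraging points implies
    class_noise_scale: float = 0.5
    fixed_effects: dict = dc_field(default_factory=lambda: {
        "sunrise_prox": 0.6, "cloud": 0.3, "temp": -0.3})
    season_window: tuple[tuple[int, int], tuple[int, int]] = ((5, 20), (7, 21))
    unclassified_rate: float = 14.0 / 1038.0
    # weather model (6-hourly AR(1) series at the colony)
    weather_ar1: float = 0.8
    weather_means: dict = dc_field(default_factory=lambda: {
        "cloud": 55.0, "temp": 12.0})
    weather_sds: dict = dc_field(default_factory=lambda: {
        "cloud": 28.0, "temp": 3.5, "wind": 4.5})
    ppt_scale: float = 2e-5
    # agricultural-field observation model
    n_transects: int = 10
    fields_per_transect: int = 5
    n_obs_periods: int = 3
    field_intercept: float = 0.6
    field_height_slope: float = -0.08       # per cm of vegetation
    field_period_effects: tuple = (0.0, -0.7, -1.4)
    field_sigma_transect: float = 0.5
    field_sigma_field: float = 1.0
    field_height_medians_cm: tuple = (12.0, 22.0, 35.0)  # per period
    field_height_lognorm_sd: float = 0.55

    def __post_init__(self):
        mix = np.asarray(self.trip_class_mixture, dtype=float)
        if (mix < 0).any():
            raise ConfigurationError("trip_class_mixture: negative entry")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"trip_class_mixture: sums to {mix.sum():.12f}, not 1")
        if self.individual_propensity_sd < 0:
            raise ConfigurationError("individual_propensity_sd: must be >= 0")
        if self.n_individuals < 0:
            raise ConfigurationError("n_individuals: must be >= 0")
        if not 0 <= self.gap_rate < 1:
            raise ConfigurationError("gap_rate: must be in [0, 1)")
        if not 0 <= self.unclassified_rate < 1:
            raise ConfigurationError("unclassified_rate: must be in [0, 1)")
        for name, med, iqr in (("duration", self.duration_medians_h,
                                self.duration_iqrs_h),
                               ("maxdist", self.maxdist_medians_km,
                                self.maxdist_iqrs_km)):
            _check_class_dict(f"{name}_medians", med)
            _check_class_dict(f"{name}_iqrs", iqr)
            for c in CLASSES:
                lo, hi = iqr[c]
                if not (0 < lo < med[c] < hi):
                    raise ConfigurationError(
                        f"{name} for class {c!r}: need 0 < q25 < median < q75")

    # -- (de)serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        kwargs = dict(d)
        for key in ("colony", "trip_class_mixture", "field_period_effects",
                    "field_height_medians_cm"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        if "season_window" in kwargs:
            kwargs["season_window"] = tuple(tuple(x) for x in kwargs["season_window"])
        for key in ("duration_iqrs_h", "maxdist_iqrs_km"):
            if key in kwargs:
                kwargs[key] = {c: tuple(v) for c, v in kwargs[key].items()}
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "Scenario":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    # -- derived quantities --------------------------------------------------
    def lognormal_params(self, which: str, cls_: str) -> tuple[float, float]:
        med = getattr(self, f"{which}_medians_h" if which == "duration"
                      else f"{which}_medians_km")[cls_]
        lo, hi = getattr(self, f"{which}_iqrs_h" if which == "duration"
                         else f"{which}_iqrs_km")[cls_]
        return math.log(med), math.log(hi / lo) / (2.0 * 0.6744897501960817)

    def season_days(self, year: int) -> pd.DatetimeIndex:
        (m0, d0), (m1, d1) = self.season_window
        return pd.date_range(pd.Timestamp(year, m0, d0, tz="UTC"),
                             pd.Timestamp(year, m1, d1, tz="UTC"), freq="D")


def standard_scenario(seed: int = 0, **overrides) -> Scenario:
    """The standard scenario S1 with an explicit seed."""
    return Scenario(seed=seed, **overrides)


@dataclass
class SyntheticWorld:
    land_mask: LandMask
    weather: WeatherSeries
    nests: pd.DataFrame  # individual_id, nest_lon, nest_lat, head_bill_mm
    colony: tuple[float, float]


def _rect(lon0, lon1, lat0, lat1) -> Polygon:
    return Polygon([(lon0, lat0), (lon1, lat0), (lon1, lat1), (lon0, lat1)])


def _streams(scenario: Scenario) -> dict[str, np.random.Generator]:
    names = ["world", "weather", "tracks", "fields"]
    children = np.random.SeedSequence(scenario.seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


# ---------------------------------------------------------------------------
# world & weather
# ---------------------------------------------------------------------------

def simulate_world(scenario: Scenario) -> SyntheticWorld:
    """Deterministic two-polygon world: colony islet + mainland 7 km east."""
    rng = _streams(scenario)["world"]
    lon_c, lat_c = scenario.colony
    m_per_deg_lon = M_PER_DEG_LAT * math.cos(math.radians(lat_c))

    island_r_deg_lat = 400.0 / M_PER_DEG_LAT
    island_r_deg_lon = 400.0 / m_per_deg_lon
    island = _rect(lon_c - island_r_deg_lon, lon_c + island_r_deg_lon,
                   lat_c - island_r_deg_lat, lat_c + island_r_deg_lat)
    mainland = _rect(lon_c + 7_000.0 / m_per_deg_lon,
                     lon_c + 110_000.0 / m_per_deg_lon,
                     lat_c - 50_000.0 / M_PER_DEG_LAT,
                     lat_c + 50_000.0 / M_PER_DEG_LAT)
    mask = LandMask([island, mainland])

    n = scenario.n_individuals
    theta = rng.uniform(0, 2 * math.pi, size=n)
    r = scenario.nest_jitter_m * np.sqrt(rng.uniform(0, 1, size=n))
    nest_lon = lon_c + r * np.cos(theta) / m_per_deg_lon
    nest_lat = lat_c + r * np.sin(theta) / M_PER_DEG_LAT
    # alternate sexes; head+bill on either side of the 113.5 mm discriminant
    sexes = np.array(["female", "male"])[np.arange(n) % 2]
    hb = np.where(sexes == "female",
                  rng.normal(106.0, 2.0, size=n),
                  rng.normal(120.0, 2.0, size=n))
    hb = np.where(sexes == "female", np.minimum(hb, 112.5), np.maximum(hb, 114.5))
    nests = pd.DataFrame({
        "individual_id": [f"gull{i + 1:02d}" for i in range(n)],
        "nest_lon": nest_lon, "nest_lat": nest_lat,
        "head_bill_mm": np.round(hb, 1),
    })
    return SyntheticWorld(mask, simulate_weather(scenario), nests,
                          scenario.colony)


def simulate_weather(scenario: Scenario) -> WeatherSeries:
    """6-hourly AR(1) weather at the colony across all simulated seasons."""
    rng = _streams(scenario)["weather"]
    (m0, d0), (m1, d1) = scenario.season_window
    start = pd.Timestamp(scenario.start_year, m0, d0, tz="UTC") - pd.Timedelta(days=5)
    end = (pd.Timestamp(scenario.start_year + scenario.n_years - 1, m1, d1,
                        tz="UTC") + pd.Timedelta(days=5))
    idx = pd.date_range(start, end, freq="6h")
    n = len(idx)
    phi = scenario.weather_ar1
    innov_sd = math.sqrt(max(0.0, 1.0 - phi * phi))

    def ar1() -> np.ndarray:
        z = np.empty(n)
        z[0] = rng.normal()
        eps = rng.normal(size=n)
        for t in range(1, n):
            z[t] = phi * z[t - 1] + innov_sd * eps[t]
        return z

    z_cloud, z_temp, z_ppt0, z_we, z_wn = (ar1() for _ in range(5))
    # rain co-varies with cloud
    z_ppt = 0.6 * z_cloud + 0.8 * z_ppt0
    sds = scenario.weather_sds
    means = scenario.weather_means
    df = pd.DataFrame({
        "cloud": np.clip(means["cloud"] + sds["cloud"] * z_cloud, 0.0, 100.0),
        "temp": means["temp"] + sds["temp"] * z_temp,
        "ppt_rate": scenario.ppt_scale * np.maximum(0.0, z_ppt - 0.4),
        "wind_ew": sds["wind"] * z_we,
        "wind_ns": sds["wind"] * z_wn,
    }, index=idx)
    return WeatherSeries(df)


# ---------------------------------------------------------------------------
# track generation
# ---------------------------------------------------------------------------

def _draw_intercepts(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """Normal intercepts moment-standardised to the configured sd.

    With a 19-bird cohort the chi-square noise of a free normal sample's
    variance would dominate downstream variance-component estimates, so the
    realised cohort is standardised to mean 0 and (population) sd exactly
    ``sd`` — the cohort is the study condition, not an estimate of one.
    """
    if n == 0 or sd == 0.0:
        return np.zeros(n)
    z = rng.normal(size=n)
    if n == 1:
        return np.zeros(1)
    z = (z - z.mean()) / max(z.std(), 1e-12)
    return sd * z


def _calibrate_band_depth(scenario: Scenario, plans: list["_TripPlan"],
                          ) -> float:
    """Band depth d making the realised cohort reproduce its configured
    between-individual variance.

    Each bird's expected aggregate land rate is a closed-form function of d
    given its realised trip classes, durations (foraging-time weights) and
    mixed-band fractions:
    F_i(d) = [w_land (1-d) + w_mixed f_mixed + w_sea d] / w_total.
    d is root-found so Var_i logit F_i(d) equals individual_propensity_sd^2
    (clamped to the interior of the sea band if unattainable). With sd 0 a
    neutral mid-band depth is used.
    """
    from scipy.optimize import brentq
    from scipy.special import logit as _logit

    sd_b = scenario.individual_propensity_sd
    inds = sorted({p.individual for p in plans})
    if sd_b <= 0 or len(inds) < 2:
        return 0.02
    # foraging-time weight per trip: duration minus the commute approximation
    rows = {i: {"land": 0.0, "sea": 0.0, "mixed_w": 0.0, "mixed_wf": 0.0}
            for i in inds}
    for p in plans:
        v_c = min(25.0, max(8.0, 2.0 * p.maxdist_m / (0.45 * p.duration_s)))
        w = max(p.duration_s - 2.0 * p.maxdist_m / v_c, 0.2 * p.duration_s)
        if p.truth_class == "mixed":
            rows[p.individual]["mixed_w"] += w
            rows[p.individual]["mixed_wf"] += w * p.land_fraction
        else:
            rows[p.individual][p.truth_class] += w
    w_land = np.array([rows[i]["land"] for i in inds])
    w_sea = np.array([rows[i]["sea"] for i in inds])
    w_mix = np.array([rows[i]["mixed_w"] for i in inds])
    wf_mix = np.array([rows[i]["mixed_wf"] for i in inds])
    w_tot = w_land + w_sea + w_mix
    keep = w_tot > 0
    if keep.sum() < 2:
        return 0.02

    def var_logit_f(logit_d: float) -> float:
        d = float(expit(logit_d))
        F = (w_land[keep] * (1.0 - d) + wf_mix[keep] + w_sea[keep] * d) \
            / w_tot[keep]
        return float(np.var(_logit(np.clip(F, 1e-9, 1 - 1e-9))))

    # depth floored at 0.005 so every marine bird's expected land-point
    # count stays well above zero (aggregates must remain estimable; a
    # deeper band recreates the all-or-nothing degeneracy)
    lo, hi = float(_logit(0.005)), float(_logit(0.0399))  # variance falls in d
    target = sd_b * sd_b
    if var_logit_f(hi) >= target:
        return 0.0399
    if var_logit_f(lo) <= target:
        return 0.005
    root = brentq(lambda ld: var_logit_f(ld) - target, lo, hi, xtol=1e-10)
    return float(expit(root))


@dataclass
class _TripPlan:
    individual: int
    year: int
    t_dep: pd.Timestamp
    eta: float
    score: float = 0.0  # class-decision score (shrunken trip noise)
    truth_class: str = ""
    land_fraction: float = 0.0
    unclassified: bool = False
    duration_s: float = 0.0
    maxdist_m: float = 0.0


def _wrap_day(seconds: float) -> float:
    return seconds % 86400.0


def simulate_tracks(scenario: Scenario, world: SyntheticWorld,
                    ) -> tuple[list[Track], dict[str, pd.DataFrame]]:
    """Generate per-individual GPS tracks plus ground-truth sidecar tables.

    Returns ``(tracks, truth)`` where ``truth["trips"]`` has one row per
    generated trip (departure/return, class, land fraction, latent eta) and
    ``truth["fixes"]`` labels every emitted fix with its trip and behaviour
    (nest / commute / forage_land / forage_sea / transit).
    """
    rng = _streams(scenario)["tracks"]
    lon_c, lat_c = scenario.colony
    b = _draw_intercepts(rng, scenario.n_individuals,
                         scenario.individual_propensity_sd)
    beta = scenario.fixed_effects
    w_mean, w_sd = scenario.weather_means, scenario.weather_sds

    sunrise_cache: dict = {}

    def _sunrise(day: pd.Timestamp) -> pd.Timestamp:
        key = day.date()
        if key not in sunrise_cache:
            sunrise_cache[key] = sunrise_time(lon_c, lat_c, key)
        return sunrise_cache[key]

    # ---- pass 1: trip skeletons with latent propensities -------------------
    plans: list[_TripPlan] = []
    for i in range(scenario.n_individuals):
        for y in range(scenario.n_years):
            year = scenario.start_year + y
            days = scenario.season_days(year)
            n_trips = min(rng.poisson(scenario.trips_per_individual_year),
                          len(days))
            day_idx = np.sort(rng.choice(len(days), size=n_trips, replace=False))
            for di in day_idx:
                day = days[di]
                t_cand = day + pd.Timedelta(seconds=float(rng.uniform(0, 86400)))
                w = weather_summary(world.weather, t_cand)
                tss = (t_cand - _sunrise(day)).total_seconds() / 3600.0
                x = {
                    "sunrise_prox": sunrise_proximity(tss),
                    "cloud": (w["cloud"] - w_mean["cloud"]) / w_sd["cloud"],
                    "temp": (w["temp"] - w_mean["temp"]) / w_sd["temp"],
                }
                e_trip = float(rng.logistic())
                base = b[i] + sum(beta[k] * x[k] for k in beta)
                plans.append(_TripPlan(
                    i, year, t_cand, eta=base + e_trip,
                    score=base + scenario.class_noise_scale * e_trip))

    if not plans:
        empty = pd.DataFrame()
        return ([Track(r.individual_id, pd.DataFrame(
            columns=["timestamp_utc", "lon", "lat", "speed_ms"]))
            for r in world.nests.itertuples()],
            {"trips": empty, "fixes": empty})

    # ---- class assignment: cohort-calibrated thresholds on eta -------------
    scores = np.array([p.score for p in plans])
    p_land, p_mixed, p_sea = scenario.trip_class_mixture
    n_all = len(plans)
    n_sea = int(round(n_all * p_sea))
    n_land = min(int(round(n_all * p_land)), n_all - n_sea)
    order = np.argsort(scores, kind="stable")
    # rank-based allocation: bottom scores sea, top scores land, middle
    # mixed — the configured mixture is reproduced exactly at cohort level
    for rank, idx in enumerate(order):
        p = plans[idx]
        if rank < n_sea:
            p.truth_class = "sea"
        elif rank >= n_all - n_land:
            p.truth_class = "land"
        else:
            p.truth_class = "mixed"
    # Within-class land fractions sit at a fixed depth inside the printed
    # bands (sea < 5 %, land > 95 % are bands, not 0/100 %): a typical
    # marine trip still yields a small share of land-side points. Mixed-band
    # fractions follow the trip's class score, kept interior ([0.08, 0.92])
    # so rendering jitter cannot flip a class.
    n_mixed = n_all - n_sea - n_land
    for j, idx in enumerate(order[n_sea:n_all - n_land]):
        frac = (j + 1) / (n_mixed + 1)
        plans[idx].land_fraction = 0.08 + 0.84 * frac
    for p in plans:
        p.unclassified = bool(rng.random() < scenario.unclassified_rate)
    # ---- metrics and departure times ---------------------------------------
    for p in plans:
        mu_d, sd_d = scenario.lognormal_params("duration", p.truth_class)
        mu_m, sd_m = scenario.lognormal_params("maxdist", p.truth_class)
        p.duration_s = float(np.exp(rng.normal(mu_d, sd_d))) * 3600.0
        p.duration_s = max(p.duration_s, 1500.0)
        m_km = float(np.exp(rng.normal(mu_m, sd_m)))
        m_km = min(m_km, 90.0)
        m_km = max(m_km, 9.5 if p.truth_class in ("land", "mixed") else 5.0)
        p.maxdist_m = m_km * 1000.0
        if p.truth_class == "land":
            day = p.t_dep.floor("D")
            mu_s = (_sunrise(day) - day).total_seconds() - 3600.0
            t = _wrap_day(mu_s + rng.normal(0.0, 2.0 * 3600.0))
            p.t_dep = day + pd.Timedelta(seconds=t)

    # ---- within-band depth: calibrated on the realised cohort --------------
    depth = _calibrate_band_depth(scenario, plans)
    for p in plans:
        if p.truth_class == "land":
            p.land_fraction = 1.0 - depth
        elif p.truth_class == "sea":
            p.land_fraction = depth

    # ---- schedule: avoid overlapping trips per individual -------------------
    plans.sort(key=lambda p: (p.individual, p.t_dep))
    prev_end: dict[int, pd.Timestamp] = {}
    for p in plans:
        if p.individual in prev_end and p.t_dep < prev_end[p.individual]:
            p.t_dep = prev_end[p.individual]
        prev_end[p.individual] = (p.t_dep + pd.Timedelta(seconds=p.duration_s)
                                  + pd.Timedelta(seconds=1800))

    # ---- pass 2: render fixes ----------------------------------------------
    tracks: list[Track] = []
    truth_trip_rows: list[dict] = []
    truth_fix_frames: list[pd.DataFrame] = []
    step = scenario.sampling_interval_s
    for i, nest in enumerate(world.nests.itertuples()):
        ind_id = nest.individual_id
        rows_t, rows_lon, rows_lat, rows_beh, rows_uid = [], [], [], [], []
        my = [p for p in plans if p.individual == i]
        for tn, p in enumerate(my):
            uid = f"{ind_id}_t{tn:03d}"
            t, lon, lat, beh = _render_trip(scenario, world, p, rng, uid)
            # bracketing nest fixes
            pre = [p.t_dep - pd.Timedelta(seconds=2 * step),
                   p.t_dep - pd.Timedelta(seconds=step)]
            post = [p.t_dep + pd.Timedelta(seconds=p.duration_s + step),
                    p.t_dep + pd.Timedelta(seconds=p.duration_s + 2 * step)]
            jit = rng.uniform(-20, 20, size=8)
            rows_t += pre + list(t) + post
            rows_lon += [nest.nest_lon + jit[0] / 90_000, nest.nest_lon + jit[1] / 90_000] \
                + list(lon) + [nest.nest_lon + jit[2] / 90_000, nest.nest_lon + jit[3] / 90_000]
            rows_lat += [nest.nest_lat + jit[4] / M_PER_DEG_LAT,
                         nest.nest_lat + jit[5] / M_PER_DEG_LAT] \
                + list(lat) + [nest.nest_lat + jit[6] / M_PER_DEG_LAT,
                               nest.nest_lat + jit[7] / M_PER_DEG_LAT]
            rows_beh += ["nest", "nest"] + list(beh) + ["nest", "nest"]
            rows_uid += [uid] * (len(t) + 4)
            truth_trip_rows.append({
                "trip_uid": uid, "individual_id": ind_id, "year": p.year,
                "departure_time": p.t_dep,
                "return_time": p.t_dep + pd.Timedelta(seconds=p.duration_s),
                "duration_h": p.duration_s / 3600.0,
                "maxdist_km": p.maxdist_m / 1000.0,
                "truth_class": ("unclassified" if p.unclassified
                                else p.truth_class),
                "land_fraction": p.land_fraction,
                "eta": p.eta, "intercept": b[i],
            })
        f = pd.DataFrame({"timestamp_utc": pd.DatetimeIndex(rows_t),
                          "lon": rows_lon, "lat": rows_lat})
        f = f.sort_values("timestamp_utc", kind="mergesort").reset_index(drop=True)
        beh = pd.DataFrame({"timestamp_utc": pd.DatetimeIndex(rows_t),
                            "trip_uid": rows_uid, "behavior": rows_beh}
                           ).sort_values("timestamp_utc", kind="mergesort")
        # drop the occasional duplicate instant from back-to-back trips
        keep = ~f["timestamp_utc"].duplicated()
        f, beh = f[keep.values].reset_index(drop=True), beh[keep.values]
        # logger gaps: drop short runs of fixes (never trip endpoints)
        if scenario.gap_rate > 0 and len(f) > 4:
            drop = np.zeros(len(f), dtype=bool)
            starts = np.flatnonzero(rng.random(len(f)) < scenario.gap_rate)
            for s in starts:
                run = 1 + min(int(rng.geometric(0.45)), 5)
                drop[s:s + run] = True
            protect = (beh["behavior"].to_numpy() == "nest")
            # also protect fixes adjacent to nest fixes (trip first/last fix)
            adj = np.zeros(len(f), dtype=bool)
            adj[1:] |= protect[:-1]
            adj[:-1] |= protect[1:]
            drop &= ~(protect | adj)
            f, beh = f[~drop].reset_index(drop=True), beh[~drop]
        # instrument speed = displacement / elapsed, assigned to later fix
        spd = np.zeros(len(f))
        if len(f) > 1:
            d = haversine_m(f["lon"].to_numpy()[:-1], f["lat"].to_numpy()[:-1],
                            f["lon"].to_numpy()[1:], f["lat"].to_numpy()[1:])
            dt = np.diff(f["timestamp_utc"].astype("int64").to_numpy()) / 1e9
            spd[1:] = np.asarray(d) / dt
        f["speed_ms"] = spd
        tracks.append(Track(ind_id, f))
        fixtable = beh.copy()
        fixtable.insert(0, "individual_id", ind_id)
        truth_fix_frames.append(fixtable.reset_index(drop=True))

    truth = {
        "trips": pd.DataFrame(truth_trip_rows),
        "fixes": (pd.concat(truth_fix_frames, ignore_index=True)
                  if truth_fix_frames else pd.DataFrame()),
    }
    return tracks, truth


def _walk(rng, t_grid, start_lon, start_lat, target_lon, target_lat, lat_ref,
          v_lo, v_hi):
    """Slow foraging walk around a target; returns lon/lat at each instant."""
    m_lon = M_PER_DEG_LAT * math.cos(math.radians(lat_ref))
    lon, lat = start_lon, start_lat
    out_lon, out_lat = [], []
    prev_t = t_grid[0] - (t_grid[1] - t_grid[0] if len(t_grid) > 1 else 300.0)
    for t in t_grid:
        dt = t - prev_t
        v = rng.uniform(v_lo, v_hi)
        d_t = math.hypot((target_lon - lon) * m_lon,
                         (target_lat - lat) * M_PER_DEG_LAT)
        if d_t > 600.0:
            base = math.atan2((target_lon - lon) * m_lon,
                              (target_lat - lat) * M_PER_DEG_LAT)
            heading = base + rng.uniform(-0.6, 0.6)
        else:
            heading = rng.uniform(0, 2 * math.pi)
        lon += v * dt * math.sin(heading) / m_lon
        lat += v * dt * math.cos(heading) / M_PER_DEG_LAT
        out_lon.append(lon)
        out_lat.append(lat)
        prev_t = t
    return out_lon, out_lat


def _land_target(world: SyntheticWorld, rng, lon_c, lat_c, dist_m, uid):
    dist_m = max(dist_m, 9500.0)
    dev_max = min(25.0, math.degrees(math.acos(min(1.0, 9200.0 / dist_m))))
    for attempt in range(3):
        dev = rng.uniform(-dev_max, dev_max) if attempt < 2 else 0.0
        tl_lon, tl_lat = destination_point(lon_c, lat_c, 90.0 + dev, dist_m)
        if world.land_mask.contains(tl_lon, tl_lat):
            return float(tl_lon), float(tl_lat)
    raise GenerationError(f"trip {uid}: no land target at {dist_m / 1000:.1f} km")


def _render_trip(scenario: Scenario, world: SyntheticWorld, p: _TripPlan,
                 rng: np.random.Generator, uid: str):
    """Rasterise one trip into fixes: commutes, foraging bout(s), return.

    Fix slots are allocated as contiguous index blocks (out-commute, sea
    bout, transfer, land bout, return) so the number of land-foraging fixes
    realises the trip's land fraction exactly, via stochastic rounding
    clamped inside the trip's class band.
    """
    lon_c, lat_c = scenario.colony
    D = p.duration_s
    M = p.maxdist_m
    step = scenario.sampling_interval_s
    N = max(int((D - 0.5 * step) // step), 4)

    # -- foraging targets ----------------------------------------------------
    f = p.land_fraction
    if p.truth_class == "land":
        land_tg = _land_target(world, rng, lon_c, lat_c, M, uid)
        sea_tg = None if f >= 1.0 else tuple(
            float(v) for v in destination_point(
                lon_c, lat_c, rng.uniform(200.0, 340.0),
                rng.uniform(3500.0, 6000.0)))
    elif p.truth_class == "sea":
        sea_tg = tuple(float(v) for v in destination_point(
            lon_c, lat_c, rng.uniform(200.0, 340.0), M))
        land_tg = None if f <= 0.0 else _land_target(world, rng, lon_c, lat_c,
                                                     9500.0, uid)
    else:
        land_tg = _land_target(world, rng, lon_c, lat_c, M, uid)
        sea_tg = tuple(float(v) for v in destination_point(
            lon_c, lat_c, rng.uniform(200.0, 340.0),
            rng.uniform(3500.0, 6000.0)))

    # -- leg lengths and fix-slot budget -------------------------------------
    waypoints = [(lon_c, lat_c)]
    if sea_tg is not None:
        waypoints.append(sea_tg)
    if land_tg is not None:
        waypoints.append(land_tg)
    waypoints.append((lon_c, lat_c))
    seg_len = [float(haversine_m(a[0], a[1], c[0], c[1]))
               for a, c in zip(waypoints[:-1], waypoints[1:])]
    total_len = sum(seg_len)
    v_c = min(25.0, max(8.0, total_len / (0.45 * D)))
    n_legs = [max(1, int(round(L / (v_c * step)))) for L in seg_len]
    m = N - sum(n_legs)  # bout fix slots
    if m < 2:
        # duration too short for the planned route: pull targets inward
        shrink = max(0.2, (N - 2 - len(seg_len)) / max(sum(n_legs), 1))
        if land_tg is not None:
            land_tg = _land_target(world, rng, lon_c, lat_c,
                                   max(9500.0, M * shrink), uid)
        if sea_tg is not None:
            d_sea = max(3500.0, float(haversine_m(lon_c, lat_c, *sea_tg))
                        * shrink)
            sea_tg = tuple(float(v) for v in destination_point(
                lon_c, lat_c, rng.uniform(200.0, 340.0), d_sea))
        waypoints = [(lon_c, lat_c)] \
            + [t for t in (sea_tg, land_tg) if t is not None] \
            + [(lon_c, lat_c)]
        seg_len = [float(haversine_m(a[0], a[1], c[0], c[1]))
                   for a, c in zip(waypoints[:-1], waypoints[1:])]
        v_c = 25.0
        n_legs = [max(1, int(round(L / (v_c * step)))) for L in seg_len]
        m = max(N - sum(n_legs), 2)

    # -- land-fix count: stochastic rounding clamped inside the class band --
    if p.truth_class == "sea":
        raw = f * m
        k = int(raw) + (1 if rng.random() < raw - int(raw) else 0)
        k = min(k, max(0, math.floor(0.05 * (m - 3) - 1e-9)))
    elif p.truth_class == "land":
        raw = (1.0 - f) * m
        s = int(raw) + (1 if rng.random() < raw - int(raw) else 0)
        s = min(s, max(0, math.floor(0.05 * (m - 3) - 1e-9)))
        k = m - s
    else:
        k = int(np.clip(round(f * m), math.ceil(0.08 * m),
                        math.floor(0.92 * m)))
    if sea_tg is not None and land_tg is not None:
        if k == 0:
            return _render_simple(scenario, p, rng, sea_tg, "forage_sea", N)
        if k == m:
            return _render_simple(scenario, p, rng, land_tg, "forage_land", N)

    # -- assemble index blocks -----------------------------------------------
    blocks = []  # (count, kind, payload)
    leg_i = 0
    blocks.append((n_legs[leg_i], "commute", (waypoints[0], waypoints[1])))
    if sea_tg is not None and land_tg is not None:
        blocks.append((m - k, "forage_sea", sea_tg))
        leg_i += 1
        blocks.append((n_legs[leg_i], "commute", (sea_tg, land_tg)))
        blocks.append((k, "forage_land", land_tg))
    elif sea_tg is not None:
        blocks.append((m, "forage_sea", sea_tg))
    else:
        blocks.append((m, "forage_land", land_tg))
    leg_i += 1
    blocks.append((n_legs[leg_i], "commute", (waypoints[-2], waypoints[-1])))
    return _rasterise(scenario, p, rng, blocks, lat_c)


def _render_simple(scenario, p, rng, target, kind, N):
    """Single-bout fallback when a planned second bout realises zero fixes."""
    lon_c, lat_c = scenario.colony
    step = scenario.sampling_interval_s
    L = float(haversine_m(lon_c, lat_c, target[0], target[1]))
    v_c = min(25.0, max(8.0, 2.0 * L / (0.45 * p.duration_s)))
    n_leg = max(1, int(round(L / (v_c * step))))
    m = max(N - 2 * n_leg, 2)
    blocks = [(n_leg, "commute", ((lon_c, lat_c), target)),
              (m, kind, target),
              (n_leg, "commute", (target, (lon_c, lat_c)))]
    return _rasterise(scenario, p, rng, blocks, lat_c)


def _rasterise(scenario: Scenario, p: _TripPlan, rng, blocks, lat_ref):
    """Positions/behaviours for contiguous fix-index blocks."""
    step = scenario.sampling_interval_s
    N = sum(c for c, _, _ in blocks)
    t_rel = step * np.arange(1, N + 1)
    lon = np.empty(N)
    lat = np.empty(N)
    beh = np.empty(N, dtype=object)
    slow_lo, slow_hi = (4.5, 7.0) if p.unclassified else (0.4, 3.2)
    i = 0
    prev_pos = None  # commute legs depart from the bird's actual position
    for count, kind, payload in blocks:
        if count <= 0:
            continue
        sl = slice(i, i + count)
        if kind == "commute":
            (a_lon, a_lat), (c_lon, c_lat) = payload
            if prev_pos is not None:
                a_lon, a_lat = prev_pos
            frac = np.arange(1, count + 1) / count  # arrive at the endpoint
            lon[sl] = a_lon + frac * (c_lon - a_lon)
            lat[sl] = a_lat + frac * (c_lat - a_lat)
            beh[sl] = "transit" if p.unclassified else "commute"
        else:
            tg_lon, tg_lat = payload
            wl, wa = _walk(rng, t_rel[sl], tg_lon, tg_lat, tg_lon, tg_lat,
                           lat_ref, slow_lo, slow_hi)
            lon[sl], lat[sl] = wl, wa
            beh[sl] = "transit" if p.unclassified else kind
        prev_pos = (lon[i + count - 1], lat[i + count - 1])
        i += count
    times = p.t_dep + pd.to_timedelta(t_rel, unit="s")
    return list(times), list(lon), list(lat), list(beh)


# ---------------------------------------------------------------------------
# field observations
# ---------------------------------------------------------------------------

def simulate_field_observations(scenario: Scenario) -> pd.DataFrame:
    """Synthetic agricultural-field survey: presence of lesser black-backed
    gulls plus co-occurring species, vegetation and earthworm counts.

    Design: ``n_transects`` roadside transects each bordering
    ``fields_per_transect`` fields, every field observed in each of three
    6-day periods both morning and evening (10 x 5 x 3 x 2 = 300 rows at the
    defaults). Vegetation height rises in median across periods with large
    within-period spread; gull presence follows a logistic model with a
    height slope, period effects and nested transect/field intercepts.
    """
    rng = _streams(scenario)["fields"]
    crops = ["cereal", "grass", "roots", "ryegrass", "other"]
    cover_classes = ["0-25%", "25-50%", "50-75%", "75-100%"]
    nt, nf, nper = (scenario.n_transects, scenario.fields_per_transect,
                    scenario.n_obs_periods)
    u_t = rng.normal(0.0, scenario.field_sigma_transect, size=nt)
    v_f = rng.normal(0.0, scenario.field_sigma_field, size=nt * nf)
    crop_of_field = rng.choice(len(crops), size=nt * nf)

    rows = []
    for ti in range(nt):
        for fi in range(nf):
            fid = ti * nf + fi
            for per in range(nper):
                mu = math.log(scenario.field_height_medians_cm[per])
                quad_h = np.exp(rng.normal(mu, scenario.field_height_lognorm_sd,
                                           size=5))
                quad_cov = np.clip(rng.normal(20.0 + 25.0 * per, 18.0, size=5),
                                   0.0, 100.0)
                veg_height, cover_class = summarize_vegetation(quad_h, quad_cov)
                for day in ("morning", "evening"):
                    logit = (scenario.field_intercept
                             + scenario.field_height_slope * veg_height
                             + scenario.field_period_effects[per]
                             + u_t[ti] + v_f[fid])
                    present = rng.random() < expit(logit)
                    lbbg = int(1 + rng.poisson(1.2)) if present else 0
                    lam_g = math.exp(1.2 - 0.06 * veg_height)
                    lam_w = math.exp(0.9 - 0.05 * veg_height)
                    rows.append({
                        "transect_id": f"T{ti + 1:02d}",
                        "field_id": f"F{fid + 1:03d}",
                        "obs_period": per + 1,
                        "day": day,
                        "black_headed_gull": int(rng.poisson(lam_g)),
                        "common_gull": int(rng.poisson(0.7 * lam_g)),
                        "herring_gull": int(rng.poisson(0.5 * lam_g)),
                        "lesser_black_backed_gull": lbbg,
                        "lapwing": int(rng.poisson(lam_w)),
                        "oystercatcher": int(rng.poisson(0.5 * lam_w)),
                        "veg_height": float(veg_height),
                        "veg_cover_class": cover_class,
                        "crop_type": crops[crop_of_field[fid]],
                        "earthworms": int(rng.poisson(3.0)),
                    })
    df = pd.DataFrame(rows)
    df["veg_cover_class"] = pd.Categorical(df["veg_cover_class"],
                                           categories=cover_classes)
    df["crop_type"] = pd.Categorical(df["crop_type"], categories=crops)
    return df


def summarize_vegetation(quadrat_heights, quadrat_covers) -> tuple[float, str]:
    """Field/period vegetation summary from five 1 m2 quadrats.

    Height is the arithmetic mean; mean percentage cover maps to its quarter
    class with lower bounds inclusive (100 % belongs to the top class).
    """
    h = float(np.mean(np.asarray(quadrat_heights, dtype=float)))
    cov = float(np.mean(np.asarray(quadrat_covers, dtype=float)))
    if not 0.0 <= cov <= 100.0:
        raise ValueError(f"mean cover outside [0, 100]: {cov}")
    bounds = ["0-25%", "25-50%", "50-75%", "75-100%"]
    idx = min(int(cov // 25.0), 3)
    return h, bounds[idx]
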