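"""End-to-end orchestration: simulate -> segment -> classify -> annotate ->
fit -> repeatability -> fields, as one configured, logged, reproducible run.

Every stage writes its outputs under the run directory so any stage can be
re-run from the persisted inputs, and every excluded trip or row is logged
with a reason (class counts are only auditable through exclusion logs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates, fields as fields_mod, habitat, io, repeatability, synthetic
from .glmm import fit_glmm, rank_models, standardize, parse_formula
from .segmentation import FilterConfig, filter_trips, interpolate_trip, segment_trips

log = logging.getLogger("gullforage")

#: trip model set mirroring the temporal/weather candidate structure
DEFAULT_TRIP_MODELS = {
    "intercept": "",
    "cloud + temp": "cloud + temp",
    "cloud + temp + ppt": "cloud + temp + ppt",
    "stage + cloud + temp + ppt + temp*stage": "stage + cloud + temp + ppt + temp*stage",
    "stage + cloud + temp + ppt": "stage + cloud + temp + ppt",
    "sunrise_prox": "sunrise_prox",
    "stage + sunrise_prox": "stage + sunrise_prox",
    "stage + cloud + temp + ppt + sunrise_prox": "stage + cloud + temp + ppt + sunrise_prox",
    "cloud + temp + ppt + sunrise_prox": "cloud + temp + ppt + sunrise_prox",
    "stage + cloud + temp + sunrise_prox": "stage + cloud + temp + sunrise_prox",
    "cloud + temp + sunrise_prox": "cloud + temp + sunrise_prox",
}

BEST_TRIP_MODEL = "cloud + temp + sunrise_prox"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending input."""


@dataclass
class RunConfig:
    out_dir: str = "run"
    scenario: dict | None = None          # simulate when set ...
    fixes: str | None = None              # ... else read these inputs
    nests: str | None = None
    mask: str | None = None
    weather: str | None = None
    field_obs: str | None = None
    colony: tuple[float, float] | None = None
    filter: dict = dc_field(default_factory=dict)
    v_low: float = habitat.V_LOW_DEFAULT
    v_high: float = habitat.V_HIGH_DEFAULT
    min_dist_km: float = habitat.MIN_DIST_KM_DEFAULT
    interp_step_s: float = 300.0
    max_gap_s: float = 2700.0
    trip_models: dict = dc_field(default_factory=lambda: dict(DEFAULT_TRIP_MODELS))
    best_model: str = BEST_TRIP_MODEL
    repeatability_iters: int = 1000
    bootstrap_iters: int = 1000
    seed: int = 0
    run_fields: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(**d)
        if cfg.scenario is None:
            for key in ("fixes", "nests", "mask", "weather", "colony"):
                if getattr(cfg, key) is None:
                    raise PipelineError(f"config missing {key!r} "
                                        "(no scenario to simulate from either)")
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def segment_and_classify(tracks: list[io.Track], nests: pd.DataFrame,
                         colony: tuple[float, float], mask: io.LandMask,
                         rules: FilterConfig | None = None,
                         v_low: float = habitat.V_LOW_DEFAULT,
                         v_high: float = habitat.V_HIGH_DEFAULT,
                         min_dist_km: float = habitat.MIN_DIST_KM_DEFAULT,
                         interp_step_s: float = 300.0,
                         max_gap_s: float = 2700.0,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tracks to classified trip records (+ exclusion log).

    Per individual: fill missing speeds, segment around the nest, filter on
    the raw trips, then interpolate to the regular grid and classify.
    """
    nest_by_ind = nests.set_index("individual_id")
    rules = rules or FilterConfig()
    all_records, logs = [], []
    for track in tracks:
        if track.individual_id not in nest_by_ind.index:
            raise PipelineError(f"segment: no nest for {track.individual_id}")
        nest = (float(nest_by_ind.loc[track.individual_id, "nest_lon"]),
                float(nest_by_ind.loc[track.individual_id, "nest_lat"]))
        trips = segment_trips(io.derive_speed(track), nest)
        kept, excl = filter_trips(trips, rules, colony)
        logs.append(excl)
        interp = [interpolate_trip(t, interp_step_s, max_gap_s) for t in kept]
        if interp:
            all_records.append(habitat.build_trip_records(
                interp, colony, mask, v_low, v_high, min_dist_km))
    records = (pd.concat(all_records, ignore_index=True)
               if all_records else pd.DataFrame())
    logs = [g for g in logs if len(g)]
    excl_log = (pd.concat(logs, ignore_index=True)
                if logs else pd.DataFrame(columns=["trip_id", "individual_id",
                                                   "departure_time", "reason"]))
    return records, excl_log


def summarize_run(records: pd.DataFrame) -> dict:
    """Trip-class counts/percentages and per-class medians."""
    n = len(records)
    counts = records["trip_class"].value_counts().to_dict()
    classified = records[records["trip_class"] != "unclassified"]
    out = {
        "n_trips": int(n),
        "n_individuals": int(records["individual_id"].nunique()) if n else 0,
        "class_counts": {c: int(counts.get(c, 0))
                         for c in ("land", "mixed", "sea", "unclassified")},
        "class_pct_of_classified": {
            c: (100.0 * counts.get(c, 0) / len(classified)) if len(classified) else np.nan
            for c in ("land", "mixed", "sea")},
        "median_duration_h": float(records["duration_h"].median()) if n else np.nan,
        "median_maxdist_km": float(records["max_distance_km"].median()) if n else np.nan,
    }
    for c in ("land", "mixed", "sea"):
        sub = records[records["trip_class"] == c]
        out[f"median_duration_h_{c}"] = float(sub["duration_h"].median()) if len(sub) else np.nan
        out[f"median_maxdist_km_{c}"] = float(sub["max_distance_km"].median()) if len(sub) else np.nan
    return out


def prepare_model_table(annotated: pd.DataFrame) -> pd.DataFrame:
    """Model-ready table: drop unclassified trips, order categoricals."""
    tab = annotated[annotated["n_forage_points"] > 0].copy()
    stages = [s for s, _, _ in covariates.STAGE_WINDOWS
              if s in set(tab["stage"])]
    tab["stage"] = pd.Categorical(tab["stage"], categories=stages)
    tab["year"] = pd.Categorical(tab["year"].astype(str),
                                 categories=sorted(tab["year"].astype(str).unique()))
    tab["sex"] = pd.Categorical(tab["sex"], categories=["female", "male"])
    return tab.reset_index(drop=True)


def _trip_formula(fixed: str) -> str:
    rhs = fixed if fixed else "1"
    return f"n_land/n_forage_points ~ {rhs} + (1|individual_id)"


def fit_trip_models(table: pd.DataFrame, models: dict[str, str] | None = None):
    models = models or dict(DEFAULT_TRIP_MODELS)
    fits = {name: fit_glmm(table, _trip_formula(fixed))
            for name, fixed in models.items()}
    return rank_models(fits), fits


def run_all(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage: inputs -----------------------------------------------------
    if config.scenario is not None:
        scen = synthetic.Scenario.from_dict({"seed": config.seed,
                                             **config.scenario})
        world = synthetic.simulate_world(scen)
        tracks, truth = synthetic.simulate_tracks(scen, world)
        mask, weather, nests = world.land_mask, world.weather, world.nests
        colony = scen.colony
        field_obs = synthetic.simulate_field_observations(scen)
        io.write_fixes(tracks, out / "fixes.csv")
        io.write_mask(mask, out / "land_mask.geojson")
        io.write_weather(weather, out / "weather.csv")
        nests.to_csv(out / "individuals.csv", index=False)
        truth["trips"].to_csv(out / "truth_trips.csv", index=False)
        field_obs.to_csv(out / "field_observations.csv", index=False)
    else:
        for key in ("fixes", "nests", "mask", "weather", "colony"):
            if getattr(config, key) is None:
                raise PipelineError(f"inputs: config missing {key!r}")
        tracks = io.read_fixes(config.fixes)
        nests = pd.read_csv(config.nests, dtype={"individual_id": str})
        mask = io.read_mask(config.mask)
        weather = io.read_weather(config.weather)
        colony = tuple(config.colony)
        field_obs = (pd.read_csv(config.field_obs)
                     if config.field_obs else None)

    # ---- stage: segment + classify ----------------------------------------
    rules = FilterConfig(**config.filter)
    records, excl = segment_and_classify(
        tracks, nests, colony, mask, rules, config.v_low, config.v_high,
        config.min_dist_km, config.interp_step_s, config.max_gap_s)
    if records.empty:
        raise PipelineError("segment: no trips survived filtering")
    io.write_trip_records(records, out / "trip_records.csv")
    excl.to_csv(out / "excluded_trips.csv", index=False)

    # ---- stage: annotate ---------------------------------------------------
    annotated = covariates.annotate_trips(records, weather, nests, colony)
    io.write_trip_records(annotated, out / "annotated.csv")

    # ---- stage: fit --------------------------------------------------------
    table = prepare_model_table(annotated)
    ranking, fits = fit_trip_models(table, config.trip_models)
    (out / "fits").mkdir(exist_ok=True)
    ranking.to_csv(out / "fits" / "ranking.csv", index=False)
    for name, f in fits.items():
        safe = name.replace(" ", "").replace("*", "x").replace("+", "_")
        io.write_fit_report({
            "model": name, "formula": f.spec.formula,
            "beta": f.beta.to_dict(), "var_components": f.var_components,
            "loglik": f.loglik, "n_obs": f.n_obs, "df": f.k_params,
            "AICc": f.aicc, "R2m": f.r2_marginal, "R2c": f.r2_conditional,
            "kappa": f.kappa, "converged": f.converged,
        }, out / "fits" / f"{safe}.json")

    # ---- stage: repeatability (standardised best model) --------------------
    best_fixed = (config.trip_models or DEFAULT_TRIP_MODELS)[config.best_model]
    spec = parse_formula(_trip_formula(best_fixed))
    std_table, _ = standardize(table, spec)
    rep = repeatability.repeatability_analysis(
        std_table, spec, n_iter=config.repeatability_iters,
        seed=config.seed + 1,
        with_randomization=config.repeatability_iters > 0,
        with_bootstrap=config.bootstrap_iters > 0)
    io.write_fit_report(rep.to_dict(), out / "repeatability.json")

    # ---- stage: fields -----------------------------------------------------
    if config.run_fields and field_obs is not None:
        ftab = fields_mod.derive_presence(field_obs)
        f_rank, _ = fields_mod.fit_field_models(
            ftab, best_for_association="veg.height + obs.per")
        (out / "field_fits").mkdir(exist_ok=True)
        f_rank.to_csv(out / "field_fits" / "ranking.csv", index=False)

    # ---- manifest + summary ------------------------------------------------
    cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "n_tracks": len(tracks),
        "n_trips_retained": int(len(records)),
        "n_trips_excluded": int(len(excl)),
    }
    io.write_fit_report(manifest, out / "manifest.json")
    summary = summarize_run(records)
    summary["repeatability"] = rep.to_dict()
    summary["best_model_AICc_rank"] = ranking["model"].tolist()
    io.write_fit_report(summary, out / "summary.json")
    return out
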