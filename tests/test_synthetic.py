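"""The synthetic world/track/weather/field generator and its calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from gullforage import synthetic
from gullforage.io import haversine_m
from gullforage.synthetic import (ConfigurationError, Scenario,
                                  simulate_field_observations,
                                  simulate_tracks, simulate_weather,
                                  simulate_world, standard_scenario,
                                  summarize_vegetation)

PI2_3 = math.pi ** 2 / 3.0


class TestScenarioValidation:
    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="trip_class_mixture"):
            Scenario(trip_class_mixture=(0.5, 0.2, 0.2))

    def test_negative_mixture_entry_rejected(self):
        with pytest.raises(ConfigurationError, match="trip_class_mixture"):
            Scenario(trip_class_mixture=(-0.1, 0.4, 0.7))

    def test_iqr_must_bracket_median(self):
        with pytest.raises(ConfigurationError, match="duration"):
            Scenario(duration_medians_h={"land": 2.0, "sea": 3.9,
                                         "mixed": 11.3})

    def test_negative_propensity_sd_rejected(self):
        with pytest.raises(ConfigurationError, match="individual_propensity_sd"):
            Scenario(individual_propensity_sd=-1.0)

    def test_yaml_roundtrip(self, tmp_path):
        import yaml
        scen = standard_scenario(seed=9)
        (tmp_path / "s.yaml").write_text(yaml.safe_dump(scen.to_dict()))
        back = Scenario.from_yaml(tmp_path / "s.yaml")
        assert back == scen


class TestWorld:
    def test_deterministic_for_fixed_seed(self):
        s = standard_scenario(seed=42)
        w1, w2 = simulate_world(s), simulate_world(s)
        pd.testing.assert_frame_equal(w1.nests, w2.nests)
        pd.testing.assert_frame_equal(w1.weather.data, w2.weather.data)
        assert [g.wkt for g in w1.land_mask.polygons] == \
               [g.wkt for g in w2.land_mask.polygons]

    def test_zero_individuals_gives_empty_nests(self):
        w = simulate_world(standard_scenario(seed=1, n_individuals=0))
        assert len(w.nests) == 0

    def test_nests_within_jitter_of_colony(self):
        s = standard_scenario(seed=3)
        w = simulate_world(s)
        d = haversine_m(w.nests["nest_lon"].to_numpy(),
                        w.nests["nest_lat"].to_numpy(), *s.colony)
        assert (np.asarray(d) <= s.nest_jitter_m + 1e-6).all()

    def test_island_contains_every_nest(self):
        w = simulate_world(standard_scenario(seed=3))
        island = w.land_mask.polygons[0]
        from shapely.geometry import Point
        assert all(island.covers(Point(r.nest_lon, r.nest_lat))
                   for r in w.nests.itertuples())

    def test_mask_polygons_simple(self):
        w = simulate_world(standard_scenario(seed=3))
        assert all(g.is_valid and g.is_simple for g in w.land_mask.polygons)


class TestWeather:
    def test_cloud_clamped_to_percent_range(self):
        w = simulate_weather(standard_scenario(seed=5))
        assert w.data["cloud"].between(0, 100).all()
        assert (w.data["ppt_rate"] >= 0).all()

    def test_zero_variance_gives_constant_series(self):
        s = standard_scenario(seed=5, weather_sds={"cloud": 0.0, "temp": 0.0,
                                                   "wind": 0.0}, ppt_scale=0.0)
        w = simulate_weather(s)
        assert w.data.nunique().le(1).all()

    def test_lag1_autocorrelation_near_configured(self):
        s = standard_scenario(seed=8, weather_ar1=0.7)
        temp = simulate_weather(s).data["temp"].to_numpy()
        assert len(temp) >= 400
        rho = np.corrcoef(temp[:-1], temp[1:])[0, 1]
        assert rho == pytest.approx(0.7, abs=0.15)


class TestTracks:
    def test_pure_land_mixture_yields_only_land_classes(self):
        s = standard_scenario(seed=2, n_individuals=4, n_years=1,
                              trips_per_individual_year=10,
                              trip_class_mixture=(1.0, 0.0, 0.0),
                              unclassified_rate=0.0)
        w = simulate_world(s)
        _, truth = simulate_tracks(s, w)
        assert set(truth["trips"]["truth_class"]) == {"land"}

    def test_determinism(self):
        s = standard_scenario(seed=21, n_individuals=4, n_years=1,
                              trips_per_individual_year=8)
        w = simulate_world(s)
        t1, tr1 = simulate_tracks(s, w)
        t2, tr2 = simulate_tracks(s, w)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.fixes, b.fixes)
        pd.testing.assert_frame_equal(tr1["trips"], tr2["trips"])

    def test_commute_fixes_faster_than_forage_fixes(self, s1):
        truth_fx = s1["truth"]["fixes"]
        frames = []
        for tr in s1["tracks"]:
            f = tr.fixes.copy()
            f["individual_id"] = tr.individual_id
            frames.append(f)
        fixes = pd.concat(frames).sort_values(["individual_id",
                                               "timestamp_utc"])
        dt = fixes.groupby("individual_id")["timestamp_utc"].diff() \
            .dt.total_seconds()
        fixes = fixes[dt <= 360]  # regular cadence: no gap/nest-stay spans
        merged = truth_fx.merge(fixes, on=["individual_id", "timestamp_utc"])
        commute_min = merged[merged["behavior"] == "commute"].groupby(
            "trip_uid")["speed_ms"].min()
        forage_max = merged[merged["behavior"].str.startswith("forage")] \
            .groupby("trip_uid")["speed_ms"].max()
        both = pd.concat([commute_min, forage_max], axis=1,
                         keys=["c", "f"]).dropna()
        assert (both["c"] > both["f"]).all()

    def test_zero_propensity_sd_gives_binomial_individual_variation(self):
        """With sd 0, between-individual spread of realised land fractions
        is compatible with multinomial class sampling (permutation check)."""
        s = standard_scenario(seed=31, n_individuals=12, n_years=1,
                              trips_per_individual_year=40,
                              individual_propensity_sd=0.0,
                              unclassified_rate=0.0)
        w = simulate_world(s)
        _, truth = simulate_tracks(s, w)
        tt = truth["trips"]
        land = (tt["truth_class"] == "land").to_numpy().astype(float)
        ind = tt["individual_id"].to_numpy()
        obs = pd.Series(land).groupby(ind).mean().var()
        rng = np.random.default_rng(0)
        perm = [pd.Series(rng.permutation(land)).groupby(ind).mean().var()
                for _ in range(199)]
        p = (1 + sum(v >= obs for v in perm)) / 200
        assert p > 0.01

    def test_latent_icc_matches_configured_repeatability(self, s1):
        tt = s1["truth"]["trips"]
        vb = tt.groupby("individual_id")["intercept"].first().var(ddof=0)
        vw = (tt["eta"] - tt["intercept"]).var(ddof=0)
        icc = vb / (vb + vw)
        target = s1["scenario"].individual_propensity_sd**2 / (
            s1["scenario"].individual_propensity_sd**2 + PI2_3)
        assert icc == pytest.approx(target, abs=0.05)

    def test_class_mixture_recovered_at_large_n(self):
        s = standard_scenario(seed=17, n_individuals=40, n_years=2,
                              trips_per_individual_year=63,
                              unclassified_rate=0.0)
        w = simulate_world(s)
        _, truth = simulate_tracks(s, w)
        tt = truth["trips"]
        n = len(tt)
        assert n >= 4500
        for cls, p in zip(("land", "mixed", "sea"), s.trip_class_mixture):
            obs = (tt["truth_class"] == cls).mean()
            ci = 3.0 * math.sqrt(p * (1 - p) / n)
            assert abs(obs - p) <= max(ci, 0.01), (cls, obs, p)

    def test_duration_lognormals_match_configured_quartiles(self):
        s = standard_scenario(seed=19, n_individuals=40, n_years=1,
                              trips_per_individual_year=55,
                              unclassified_rate=0.0)
        w = simulate_world(s)
        _, truth = simulate_tracks(s, w)
        tt = truth["trips"]
        for cls in ("land", "sea"):
            sub = tt.loc[tt["truth_class"] == cls, "duration_h"]
            assert len(sub) >= 300
            med = s.duration_medians_h[cls]
            lo, hi = s.duration_iqrs_h[cls]
            assert sub.median() == pytest.approx(med, rel=0.10)
            assert sub.quantile(0.25) == pytest.approx(lo, rel=0.12)
            assert sub.quantile(0.75) == pytest.approx(hi, rel=0.12)


class TestFieldObservations:
    def test_exactly_300_rows_at_standard_design(self):
        obs = simulate_field_observations(standard_scenario(seed=23))
        assert len(obs) == 300
        assert obs["field_id"].nunique() == 50
        assert obs["transect_id"].nunique() == 10

    def test_null_model_presence_rate_matches_intercept(self):
        from scipy.special import expit
        s = standard_scenario(seed=29, field_height_slope=0.0,
                              field_period_effects=(0.0, 0.0, 0.0),
                              field_sigma_transect=0.0, field_sigma_field=0.0,
                              field_intercept=-1.0)
        obs = simulate_field_observations(s)
        rate = (obs["lesser_black_backed_gull"] > 0).mean()
        p = expit(-1.0)
        se = math.sqrt(p * (1 - p) / len(obs))
        assert abs(rate - p) <= 4 * se

    def test_strong_height_slope_orders_presence_by_tercile(self):
        s = standard_scenario(seed=37, field_height_slope=-0.25,
                              field_sigma_transect=0.0, field_sigma_field=0.0,
                              field_intercept=2.0)
        obs = simulate_field_observations(s)
        q = obs["veg_height"].quantile([1 / 3, 2 / 3])
        short = obs[obs["veg_height"] <= q.iloc[0]]
        tall = obs[obs["veg_height"] >= q.iloc[1]]
        assert (tall["lesser_black_backed_gull"] > 0).mean() < \
               (short["lesser_black_backed_gull"] > 0).mean()

    def test_vegetation_height_rises_across_periods(self):
        obs = simulate_field_observations(standard_scenario(seed=41))
        med = obs.groupby("obs_period")["veg_height"].median()
        assert med.is_monotonic_increasing


class TestSummarizeVegetation:
    def test_mean_of_quadrats(self):
        h, _ = summarize_vegetation([0, 10, 20, 30, 40], [10] * 5)
        assert h == 20.0

    def test_constant_heights(self):
        h, _ = summarize_vegetation([10] * 5, [10] * 5)
        assert h == 10.0

    @pytest.mark.parametrize("cov,cls", [
        (10.0, "0-25%"), (25.0, "25-50%"), (50.0, "50-75%"),
        (75.0, "75-100%"), (100.0, "75-100%"),
    ])
    def test_cover_class_lower_inclusive(self, cov, cls):
        _, c = summarize_vegetation([1] * 5, [cov] * 5)
        assert c == cls
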