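"""Shared fixtures: the standard synthetic scenario S1 run end to end once
per session, plus small helper builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gullforage import covariates, pipeline, synthetic

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

S1_SEED = 1


@pytest.fixture(scope="session")
def s1():
    """Standard scenario S1 generated and pushed through the pipeline."""
    scen = synthetic.standard_scenario(seed=S1_SEED)
    world = synthetic.simulate_world(scen)
    tracks, truth = synthetic.simulate_tracks(scen, world)
    records, excl = pipeline.segment_and_classify(
        tracks, world.nests, scen.colony, world.land_mask)
    annotated = covariates.annotate_trips(records, world.weather,
                                          world.nests, scen.colony)
    table = pipeline.prepare_model_table(annotated)
    return {"scenario": scen, "world": world, "tracks": tracks,
            "truth": truth, "records": records, "excluded": excl,
            "annotated": annotated, "table": table}


@pytest.fixture()
def colony():
    return (17.9667, 57.2833)


def make_track(times_s, lons, lats, speeds=None, individual="bird1"):
    """Build a Track from relative seconds and coordinate lists."""
    from gullforage.io import Track
    t0 = pd.Timestamp("2012-06-01 00:00:00", tz="UTC")
    n = len(times_s)
    return Track(individual, pd.DataFrame({
        "timestamp_utc": [t0 + pd.Timedelta(seconds=float(s)) for s in times_s],
        "lon": np.asarray(lons, dtype=float),
        "lat": np.asarray(lats, dtype=float),
        "speed_ms": (np.full(n, np.nan) if speeds is None
                     else np.asarray(speeds, dtype=float)),
    }))


@pytest.fixture()
def square_mask():
    """One unit square land polygon centred on (10, 50)."""
    from shapely.geometry import Polygon
    from gullforage.io import LandMask
    return LandMask([Polygon([(9.5, 49.5), (10.5, 49.5),
                              (10.5, 50.5), (9.5, 50.5)])])
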