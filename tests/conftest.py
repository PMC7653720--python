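import logging

import numpy as np
import pandas as pd
import pytest

import colonyforage as cf
from colonyforage.geo import AzimuthalEquidistant, square_colony

logging.getLogger("colonyforage").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_dataset():
    """A small noise-bearing simulated study used by several tests."""
    cfg = cf.SimulationConfig(
        seed=101,
        n_birds_per_group={"zb_zb": 4, "vl_vl": 3, "zb_vl": 3},
        n_days=6)
    return cfg, cf.simulate_tracks(cfg)


@pytest.fixture(scope="session")
def noisefree_dataset():
    """Noise-free tracks: segmentation should match the truth log exactly."""
    cfg = cf.SimulationConfig(
        seed=7,
        n_birds_per_group={"zb_zb": 2, "vl_vl": 2, "zb_vl": 2},
        n_days=4, gps_noise_sd_m=0.0)
    return cfg, cf.simulate_tracks(cfg)


@pytest.fixture()
def colony():
    return square_colony("c", (3.5, 51.4), halfwidth_m=250.0)


def make_trajectory(colony, legs, t0="2016-06-01T06:00:00+00:00",
                    bird_id="b1"):
    """Build a trajectory from (minutes, x_km, y_km) waypoints sampled
    exactly (plane centred on the colony centre)."""
    proj = AzimuthalEquidistant(*colony.center)
    t0 = pd.Timestamp(t0)
    rows = []
    for minutes, x, y in legs:
        lon, lat = proj.inverse(np.array([x]), np.array([y]))
        rows.append({"bird_id": bird_id,
                     "timestamp": t0 + pd.Timedelta(minutes=minutes),
                     "lon": float(lon[0]), "lat": float(lat[0])})
    return pd.DataFrame(rows)


@pytest.fixture()
def make_traj():
    return make_trajectory
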