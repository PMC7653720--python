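import numpy as np
import pandas as pd
import pytest

import colonyforage as cf
from colonyforage.geo import haversine_km
from colonyforage.simulate import logistic_mass


def _one_site_config(dist_km=20.0, **kw):
    """One bird, one group, a single foraging site `dist_km` east."""
    from colonyforage.geo import AzimuthalEquidistant
    center = (3.5, 51.4)
    proj = AzimuthalEquidistant(*center)
    lon, lat = proj.inverse(np.array([dist_km]), np.array([0.0]))
    base = dict(seed=5, groups=("g",), n_birds_per_group=1,
                colony_centers={"c": center}, colony_of_group={"g": "c"},
                foraging_sites={"g": [(float(lon[0]), float(lat[0]), 1.0)]},
                growth_groups=(), nests_per_group_brood={},
                adult_n_males={"g": 3}, adult_mass_mean={"g": 900.0},
                adult_mass_sd={"g": 50.0},
                site_fidelity_alpha=0.0, bird_rate_sd=0.0, bird_dwell_sd=0.0)
    base.update(kw)
    return cf.SimulationConfig(**base)


class TestTracks:
    def test_no_trips_keeps_all_fixes_in_colony(self):
        cfg = _one_site_config(trips_per_day=0.0, n_days=2)
        ds = cf.simulate_tracks(cfg)
        assert len(ds.truth_trips) == 0
        inside = ds.colonies["c"].contains(ds.fixes["lon"], ds.fixes["lat"])
        assert inside.all()

    def test_single_trip_reaches_site_distance(self):
        cfg = _one_site_config(dist_km=20.0, trips_per_day=1.0, n_days=1,
                               seed=12, gps_noise_sd_m=10.0,
                               dwell_jitter_km=0.0)
        ds = cf.simulate_tracks(cfg)
        # Poisson(1) may produce 0 or >1 departures; find a seed giving 1
        s = 12
        while len(ds.truth_trips) != 1:
            s += 1
            ds = cf.simulate_tracks(_one_site_config(
                dist_km=20.0, trips_per_day=1.0, n_days=1, seed=s,
                gps_noise_sd_m=10.0, dwell_jitter_km=0.0))
        d = haversine_km(ds.fixes["lon"], ds.fixes["lat"], 3.5, 51.4)
        # furthest fix is at the site, up to GPS noise (4 sd bound)
        assert d.max() == pytest.approx(20.0, abs=0.05)

    def test_equal_seeds_reproduce_fix_table(self):
        cfg = cf.SimulationConfig(
            seed=9, n_birds_per_group={"zb_zb": 2, "vl_vl": 1, "zb_vl": 1},
            n_days=2)
        a = cf.simulate_tracks(cfg)
        b = cf.simulate_tracks(cfg)
        pd.testing.assert_frame_equal(a.fixes, b.fixes)
        pd.testing.assert_frame_equal(a.truth_trips, b.truth_trips)

    def test_fix_distance_bounded_by_site_plus_jitter(self, small_dataset):
        cfg, ds = small_dataset
        for (bird, colony), sub in ds.fixes.merge(
                ds.birds, on="bird_id").groupby(["bird_id", "colony"]):
            center = cfg.colony_centers[colony]
            d = haversine_km(sub["lon"], sub["lat"], *center)
            sites = cfg.foraging_sites[sub["group_x"].iloc[0]
                                       if "group_x" in sub else
                                       sub["group"].iloc[0]]
            dmax = max(haversine_km(lo, la, *center) for lo, la, _ in sites)
            bound = dmax + 6 * cfg.dwell_jitter_km \
                + 6 * cfg.gps_noise_sd_m / 1000.0 + 0.5
            assert d.max() <= bound

    def test_rejects_group_without_sites(self):
        with pytest.raises(ValueError, match="foraging sites"):
            _one_site_config(foraging_sites={"g": []})

    def test_truth_log_matches_resegmentation_when_noise_free(
            self, noisefree_dataset):
        cfg, ds = noisefree_dataset
        _, trips_by_bird = cf.metrics_for_dataset(ds.fixes, ds.colonies,
                                                  ds.birds)
        truth_counts = ds.truth_trips.groupby("bird_id").size()
        for bird, trips in trips_by_bird.items():
            assert len(trips) == truth_counts.get(bird, 0)


class TestGrowth:
    def test_noise_free_masses_lie_on_group_curve(self):
        cfg = cf.SimulationConfig(
            seed=3, residual_sd=0.0,
            random_sd={"year": 0.0, "parent": 0.0, "nest": 0.0, "chick": 0.0},
            chick_death_prob_brood3=0.0,
            nests_per_group_brood={("vl_vl", 1): 2, ("zb_vl", 3): 2})
        rec, truth = cf.simulate_growth(cfg)
        tr = truth["chicks"].set_index("chick_id")
        for cid, sub in rec.groupby("chick_id"):
            A, I, K = tr.loc[cid, ["A", "I", "K"]]
            np.testing.assert_allclose(
                sub["mass_g"], logistic_mass(sub["age_days"], A, I, K),
                rtol=1e-12)

    def test_half_asymptote_at_inflection(self):
        assert logistic_mass(12.0, 800.0, 12.0, 0.2) == pytest.approx(400.0)

    def test_brood_by_origin_offset_on_K_is_recoverable(self):
        # the generator's true interaction offset should be visible in the
        # mean fitted K difference-in-differences
        eff = {"A": {"intercept": 850.0}, "I": {"intercept": 12.0},
               "K": {"intercept": 0.18, "brood3:zb_vl": -0.05}}
        cfg = cf.SimulationConfig(
            seed=21, growth_effects=eff, chick_death_prob_brood3=0.0,
            random_sd={"year": 0, "parent": 0, "nest": 0, "chick": 0},
            residual_sd=20.0,
            nests_per_group_brood={("vl_vl", 1): 40, ("vl_vl", 3): 25,
                                   ("zb_vl", 1): 40, ("zb_vl", 3): 25})
        rec, _ = cf.simulate_growth(cfg)
        params = cf.fit_all_chicks(rec, seed=0)
        ok = params[params["converged"]]
        m = ok.groupby(["origin", "brood_size"])["K"].mean()
        did = ((m["zb_vl", 3] - m["zb_vl", 1])
               - (m["vl_vl", 3] - m["vl_vl", 1]))
        assert did == pytest.approx(-0.05, abs=0.012)

    def test_deaths_truncate_series_only_in_large_broods(self):
        cfg = cf.SimulationConfig(seed=8, chick_death_prob_brood3=0.9)
        rec, truth = cf.simulate_growth(cfg)
        per_chick = rec.groupby("chick_id").agg(
            n=("age_days", "size"), brood=("brood_size", "first"))
        assert (per_chick.loc[per_chick["brood"] == 1, "n"] == 16).all()
        assert (per_chick.loc[per_chick["brood"] == 3, "n"] < 16).any()

    def test_adult_masses_grouped_with_requested_sizes(self):
        cfg = cf.SimulationConfig(seed=4)
        adults = cf.simulate_adult_masses(cfg)
        assert adults.groupby("origin").size().to_dict() == {
            "zb_zb": 14, "vl_vl": 6, "zb_vl": 7}

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            cf.SimulationConfig(fix_interval=0)
        with pytest.raises(ValueError):
            cf.SimulationConfig(n_days=0)
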