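import numpy as np
import pandas as pd
import pytest

from colonyforage import lmm, trips


def outback_legs(dist_km=20.0, step_min=3.0, n_steps=10, t_start=0.0):
    """Out-and-back along +x: exact fixes, path = 2 * dist by construction."""
    legs = []
    for i in range(n_steps + 1):
        legs.append((t_start + i * step_min, dist_km * i / n_steps, 0.0))
    for i in range(1, n_steps + 1):
        legs.append((t_start + (n_steps + i) * step_min,
                     dist_km * (n_steps - i) / n_steps, 0.0))
    return legs


class TestSegmentation:
    def test_all_inside_yields_no_trips(self, colony, make_traj):
        traj = make_traj(colony, [(i * 3, 0.01 * i, 0.0) for i in range(10)])
        assert trips.segment_trips(traj, colony) == []

    def test_short_trajectory_yields_no_trips(self, colony, make_traj):
        traj = make_traj(colony, [(0, 0, 0)])
        assert trips.segment_trips(traj, colony) == []

    def test_filter_drops_short_and_near_excursions_only(self, colony,
                                                         make_traj):
        legs = outback_legs(5.0, 3.0, 5, t_start=0)            # 30 min, 5 km
        legs += [(40 + m, 0.5 if m in (3, 6) else 0.0, 0.0)    # 9 min, 0.5 km
                 for m in (0, 3, 6, 9)]
        legs += outback_legs(10.0, 3.0, 10, t_start=60)        # 60 min, 10 km
        traj = make_traj(colony, legs)
        got = trips.segment_trips(traj, colony)
        assert len(got) == 2
        assert [round(t.max_distance_km) for t in got] == [5, 10]

    def test_both_filter_conditions_must_hold_to_exclude(self, colony,
                                                         make_traj):
        # long but near: 45 min within 0.6 km -> retained
        legs = [(m, 0.6 if 0 < m < 45 else 0.0, 0.0)
                for m in range(0, 48, 3)]
        traj = make_traj(colony, legs)
        assert len(trips.segment_trips(traj, colony)) == 1
        # short but far: 12 min to 3 km -> retained
        legs = [(0, 0, 0), (3, 1.5, 0), (6, 3.0, 0), (9, 1.5, 0), (12, 0, 0)]
        traj = make_traj(colony, legs)
        assert len(trips.segment_trips(traj, colony)) == 1

    def test_invariant_to_padding_with_colony_fixes(self, colony, make_traj):
        core = outback_legs(8.0, 3.0, 8)
        pad_before = [(-30 + m, 0.0, 0.0) for m in range(0, 30, 3)]
        pad_after = [(core[-1][0] + m, 0.0, 0.01) for m in range(3, 30, 3)]
        t1 = trips.segment_trips(make_traj(colony, core), colony)
        t2 = trips.segment_trips(
            make_traj(colony, pad_before + core + pad_after), colony)
        assert len(t1) == len(t2) == 1
        assert t1[0].max_distance_km == pytest.approx(t2[0].max_distance_km)
        assert t1[0].path_km == pytest.approx(t2[0].path_km)

    def test_unbracketed_leading_excursion_discarded(self, colony, make_traj):
        legs = [(0, 5.0, 0), (3, 2.0, 0)] + outback_legs(8.0, 3.0, 8,
                                                         t_start=10)
        got = trips.segment_trips(make_traj(colony, legs), colony)
        assert len(got) == 1
        assert got[0].max_distance_km == pytest.approx(8.0, abs=0.01)

    def test_gap_flagging(self, colony, make_traj):
        legs = [(0, 0, 0), (3, 5, 0), (50, 5, 1), (53, 0, 0)]
        got = trips.segment_trips(make_traj(colony, legs), colony)
        assert len(got) == 1 and got[0].gap_flagged


class TestDailyMetrics:
    def test_single_outback_loop_straightness_is_two(self, colony, make_traj):
        traj = make_traj(colony, outback_legs(20.0, 3.0, 10))
        tr = trips.segment_trips(traj, colony)
        dm = trips.daily_metrics(tr, colony)
        assert len(dm) == 1
        assert dm["straightness"].iloc[0] == pytest.approx(2.0, abs=0.02)
        assert dm["max_distance_km"].iloc[0] == pytest.approx(20.0, abs=0.01)
        assert dm["total_distance_km"].iloc[0] == pytest.approx(40.0, abs=0.02)

    def test_midnight_spanning_trip_splits_and_lowers_straightness(
            self, colony, make_traj):
        # departs 23:00 local (UTC+2), furthest point exactly at midnight
        traj = make_traj(colony, outback_legs(20.0, 6.0, 10),
                         t0="2016-06-01T21:00:00+00:00")
        tr = trips.segment_trips(traj, colony)
        assert len(tr) == 1
        dm = trips.daily_metrics(tr, colony, local_utc_offset=2.0)
        assert len(dm) == 2
        assert (dm["straightness"] < 2.0).all()
        # the furthest point belongs to the second civil date only
        assert dm["max_distance_km"].iloc[1] == pytest.approx(20.0, abs=0.01)
        assert dm["max_distance_km"].iloc[0] < 20.0

    def test_daily_durations_partition_trip_durations(self, colony,
                                                      make_traj):
        legs = (outback_legs(10.0, 3.0, 10, t_start=0)
                + outback_legs(15.0, 6.0, 10, t_start=150))
        traj = make_traj(colony, legs, t0="2016-06-01T20:00:00+00:00")
        tr = trips.segment_trips(traj, colony)
        dm = trips.daily_metrics(tr, colony)
        assert dm["duration_h"].sum() == pytest.approx(
            sum(t.duration_h for t in tr), rel=1e-9)

    def test_no_trips_empty_metrics(self, colony):
        assert trips.daily_metrics([], colony).empty

    def test_path_at_least_twice_reach_on_closed_loops(self, noisefree_dataset):
        cfg, ds = noisefree_dataset
        _, by_bird = trips.metrics_for_dataset(ds.fixes, ds.colonies,
                                               ds.birds)
        for tlist in by_bird.values():
            for t in tlist:
                # boundary-to-centre offset: half-width in km
                off = cfg.colony_halfwidth_m / 1000.0
                assert t.path_km >= 2 * (t.max_distance_km - off) - 1e-6


class TestCompareGroups:
    def _metrics(self, rng, n_birds=6, shift=0.0, group="a", start_bird=0):
        rows = []
        for b in range(n_birds):
            for d in range(12):
                rows.append({"bird_id": f"{group}{b + start_bird}",
                             "group": group, "chick_age_days": d,
                             "max_distance_km":
                                 30 + shift + rng.normal(0, 5)})
        return pd.DataFrame(rows)

    def test_identical_copies_give_zero_contrast(self):
        rng = np.random.default_rng(0)
        a = self._metrics(rng, group="a")
        b = a.copy()
        b["group"] = "b"
        b["bird_id"] = "x" + b["bird_id"]
        out = trips.compare_groups(pd.concat([a, b], ignore_index=True),
                                   responses=("max_distance_km",))
        tk = out["max_distance_km"]["tukey"]
        assert tk["estimate"].abs().max() < 1e-8

    def test_shifted_group_is_detected(self):
        rng = np.random.default_rng(1)
        a = self._metrics(rng, n_birds=8, group="a")
        b = self._metrics(rng, n_birds=8, shift=20.0, group="b")
        out = trips.compare_groups(pd.concat([a, b], ignore_index=True),
                                   responses=("max_distance_km",))
        terms = out["max_distance_km"]["terms"].set_index("term")
        assert terms.loc["group", "p"] < 0.01

    def test_single_group_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(lmm.LMMError, match="2 origin groups"):
            trips.compare_groups(self._metrics(rng),
                                 responses=("max_distance_km",))
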