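"""Foraging-trip segmentation and daily foraging metrics.

A trip starts with the last GPS fix inside the colony boundary and ends
with the first fix back inside it. Trips shorter than 30 minutes AND
reaching less than 1 km from the colony are excluded (both conditions
must hold), since such short nearby excursions are unlikely to be
foraging. Four daily metrics are computed per bird and local civil date:
maximum distance from the colony, total (cumulative point-to-point)
distance, duration away from the colony, and straightness = total /
maximum distance, which is ~2 for a single out-and-back loop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import lmm
from .geo import ColonyPolygon, haversine_km

log = logging.getLogger(__name__)


@dataclass
class Trip:
    """One foraging excursion, bracketed by inside-colony fixes."""

    bird_id: str
    start: pd.Timestamp   # last fix inside the colony before leaving
    end: pd.Timestamp     # first fix back inside
    fixes: pd.DataFrame   # bracketing fixes included
    max_distance_km: float
    path_km: float
    duration_h: float
    gap_flagged: bool = False

    def __post_init__(self):
        assert self.start < self.end


def segment_trips(traj: pd.DataFrame, poly: ColonyPolygon, *,
                  min_duration_min: float = 30.0,
                  min_distance_km: float = 1.0,
                  gap_flag_min: float = 30.0) -> list[Trip]:
    """Split one bird's trajectory into retained foraging trips.

    `traj` must be time-sorted with columns bird_id, timestamp, lon, lat.
    Leading/trailing runs outside the colony that lack an inside bracket
    are discarded (logged). Trips containing a fix gap longer than
    `gap_flag_min` minutes are retained but flagged.
    """
    if len(traj) < 2:
        return []
    lon = traj["lon"].to_numpy(dtype=float)
    lat = traj["lat"].to_numpy(dtype=float)
    ts = pd.to_datetime(traj["timestamp"].to_numpy())
    inside = poly.contains(lon, lat)
    bird = str(traj["bird_id"].iloc[0]) if "bird_id" in traj.columns else ""

    cx, cy = poly.center
    dist_center = haversine_km(lon, lat, cx, cy)

    idx_inside = np.flatnonzero(inside)
    if idx_inside.size == 0:
        log.info("bird %s: no fixes inside the colony; nothing to segment", bird)
        return []
    if idx_inside[0] > 0 or idx_inside[-1] < len(traj) - 1:
        log.info("bird %s: discarding unbracketed outside run(s) at the "
                 "track edges", bird)

    trips: list[Trip] = []
    # consecutive inside fixes with a gap between them bracket an outside run
    for a, b in zip(idx_inside[:-1], idx_inside[1:]):
        if b == a + 1:
            continue
        sl = slice(a, b + 1)
        seg_lon, seg_lat = lon[sl], lat[sl]
        seg_ts = ts[sl]
        dur_h = (seg_ts[-1] - seg_ts[0]) / np.timedelta64(1, "h")
        maxd = float(dist_center[sl].max())
        if dur_h < min_duration_min / 60.0 and maxd < min_distance_km:
            continue
        path = float(haversine_km(seg_lon[:-1], seg_lat[:-1],
                                  seg_lon[1:], seg_lat[1:]).sum())
        gaps = np.diff(seg_ts) / np.timedelta64(1, "m")
        flagged = bool((gaps > gap_flag_min).any())
        if flagged:
            log.warning("bird %s: trip starting %s has a fix gap > %g min; "
                        "retained but flagged", bird, seg_ts[0], gap_flag_min)
        trips.append(Trip(bird_id=bird,
                          start=pd.Timestamp(seg_ts[0]),
                          end=pd.Timestamp(seg_ts[-1]),
                          fixes=traj.iloc[sl].copy(),
                          max_distance_km=maxd, path_km=path,
                          duration_h=float(dur_h), gap_flagged=flagged))
    return trips


def trips_table(trips: list[Trip]) -> pd.DataFrame:
    return pd.DataFrame([{"bird_id": t.bird_id, "start": t.start,
                          "end": t.end,
                          "max_distance_km": t.max_distance_km,
                          "path_km": t.path_km, "duration_h": t.duration_h,
                          "gap_flagged": t.gap_flagged}
                         for t in trips])


def _local_date(ts, offset_h: float):
    return (pd.to_datetime(ts) + pd.Timedelta(hours=offset_h)).date()


def daily_metrics(trips: list[Trip], poly: ColonyPolygon,
                  local_utc_offset: float = 2.0) -> pd.DataFrame:
    """The four daily foraging metrics from retained trips.

    Path segments are assigned to the local civil date of their first fix;
    distances-from-colony to the date of the fix; trip durations are
    intersected with each date. Dates with no trip fixes are absent.
    A trip spanning midnight therefore contributes partial path to both
    dates while its furthest point counts only on the date it was
    reached, which is why day-level straightness can fall below 2.
    """
    if not trips:
        return pd.DataFrame(columns=["bird_id", "date", "max_distance_km",
                                     "total_distance_km", "duration_h",
                                     "straightness", "n_trips"])
    cx, cy = poly.center
    off = local_utc_offset
    maxd: dict = {}
    total: dict = {}
    dur: dict = {}
    ntrip: dict = {}
    bird = trips[0].bird_id
    for t in trips:
        lon = t.fixes["lon"].to_numpy(dtype=float)
        lat = t.fixes["lat"].to_numpy(dtype=float)
        ts = pd.to_datetime(t.fixes["timestamp"].to_numpy())
        d = haversine_km(lon, lat, cx, cy)
        dates = np.array([_local_date(x, off) for x in ts])
        for day in np.unique(dates):
            m = dates == day
            maxd[day] = max(maxd.get(day, 0.0), float(d[m].max()))
        seg = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        for day in np.unique(dates[:-1]):
            m = dates[:-1] == day
            total[day] = total.get(day, 0.0) + float(seg[m].sum())
        # duration intersected with each local date
        start, end = t.start, t.end
        day = _local_date(start, off)
        while True:
            day_start = (pd.Timestamp(day) - pd.Timedelta(hours=off)
                         ).tz_localize(start.tz)
            day_end = day_start + pd.Timedelta(days=1)
            lo, hi = max(start, day_start), min(end, day_end)
            if hi > lo:
                dur[day] = dur.get(day, 0.0) + (hi - lo) / pd.Timedelta(hours=1)
                ntrip[day] = ntrip.get(day, 0) + 1
            if end <= day_end:
                break
            day = day + pd.Timedelta(days=1)
            day = day.date() if hasattr(day, "date") else day

    rows = []
    for day in sorted(maxd):
        md = maxd[day]
        tot = total.get(day, 0.0)
        rows.append({"bird_id": bird, "date": day,
                     "max_distance_km": md, "total_distance_km": tot,
                     "duration_h": dur.get(day, 0.0),
                     "straightness": tot / md if md > 0 else np.nan,
                     "n_trips": ntrip.get(day, 0)})
    return pd.DataFrame(rows)


def metrics_for_dataset(fixes: pd.DataFrame, colonies: dict,
                        birds: pd.DataFrame,
                        local_utc_offset: float = 2.0, **seg_kw):
    """Segment every bird and assemble the pooled daily-metrics table.

    `birds` maps bird_id to group, colony and hatch_date (for chick age).
    Returns (metrics, trips_by_bird).
    """
    out, trips_by_bird = [], {}
    meta = birds.set_index("bird_id")
    for bird_id, traj in fixes.groupby("bird_id", sort=True):
        info = meta.loc[bird_id]
        poly = colonies[info["colony"]]
        trips = segment_trips(traj.sort_values("timestamp"), poly, **seg_kw)
        trips_by_bird[bird_id] = trips
        dm = daily_metrics(trips, poly, local_utc_offset)
        if len(dm):
            dm["group"] = info["group"]
            hatch = info.get("hatch_date")
            if hatch is not None and not pd.isna(hatch):
                dm["chick_age_days"] = [
                    (pd.Timestamp(d) - pd.Timestamp(hatch)).days
                    for d in dm["date"]]
            out.append(dm)
    metrics = (pd.concat(out, ignore_index=True) if out else
               pd.DataFrame(columns=["bird_id", "date", "max_distance_km",
                                     "total_distance_km", "duration_h",
                                     "straightness", "n_trips", "group",
                                     "chick_age_days"]))
    return metrics, trips_by_bird


METRIC_MODELS = {
    "max_distance_km": "max_distance_km ~ group * chick_age_days",
    "total_distance_km": "total_distance_km ~ group * chick_age_days",
    "duration_h": "duration_h ~ group * chick_age_days",
    "straightness": "straightness ~ group",
}


def compare_groups(metrics: pd.DataFrame,
                   responses: tuple[str, ...] = ("max_distance_km",
                                                 "total_distance_km",
                                                 "duration_h",
                                                 "straightness")) -> dict:
    """Mixed-model comparison of daily metrics between origin groups.

    Fits, per metric, a linear mixed model with parental origin, chick age
    and their interaction as fixed effects (origin only, for straightness)
    and bird identity as a random intercept. Returns per-metric dicts with
    the F/df/p term table, model-based group means +- SE, and
    Tukey-adjusted pairwise origin contrasts.
    """
    if metrics["group"].nunique() < 2:
        raise lmm.LMMError("need >= 2 origin groups to compare")
    out = {}
    for resp in responses:
        formula = METRIC_MODELS.get(resp, f"{resp} ~ group * chick_age_days")
        cols = ["bird_id", "group", resp]
        if "chick_age_days" in formula:
            cols.append("chick_age_days")
        df = metrics[cols].dropna().reset_index(drop=True)
        fit = lmm.fit_lmm(formula, df, random=("bird_id",))
        out[resp] = {"fit": fit,
                     "terms": lmm.term_table(fit),
                     "means": lmm.group_means(fit, "group"),
                     "tukey": lmm.tukey_pairwise(fit, "group")}
    return out
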