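"""Synthetic field data with the statistical structure the analysis assumes.

Emulates a two-colony gull system: resident birds in the old colony
(zb_zb), residents in the new colony 37 km away (vl_vl), and relocated
birds nesting in the new colony but still commuting to distant foraging
grounds near their old one (zb_vl). Birds make out-and-back foraging
trips from their colony to group-specific foraging sites, sampled as GPS
fixes every 3 minutes with isotropic Gaussian position noise. Chick
growth follows the logistic curve W_t = A / (1 + exp(K (I - t))) with
group x brood-size x sex effects on the parameters, nested random
intercepts (year, parent, nest, chick) and Gaussian residual noise.

Every stochastic stream is derived from a single seed through named
sub-streams, so tracks, growth and adult masses can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .geo import AzimuthalEquidistant, ColonyPolygon, square_colony

# printed colony coordinates (lon, lat): Vlissingen 51°27'N 3°42'E,
# Zeebrugge 51°20'N 3°10'E
COLONY_CENTERS = {
    "vl": (3.70, 51.45),
    "zb": (3.0 + 10.0 / 60.0, 51.0 + 20.0 / 60.0),
}
COLONY_OF_GROUP = {"zb_zb": "zb", "vl_vl": "vl", "zb_vl": "vl"}

_STREAMS = {"tracks": 0, "growth": 1, "adults": 2, "noise": 3}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), _STREAMS[stream], extra]))


def _default_sites() -> dict[str, list[tuple[float, float, float]]]:
    """Group-specific foraging sites as (lon, lat, weight).

    Residents of the old colony use grounds around it; residents of the
    new colony use nearer grounds; relocated birds mostly keep visiting
    the distant old grounds plus one area of their own, which makes their
    daily ranges longer and spatially intermediate.
    """
    zb = AzimuthalEquidistant(*COLONY_CENTERS["zb"])
    vl = AzimuthalEquidistant(*COLONY_CENTERS["vl"])

    def ll(proj, x, y):
        lon, lat = proj.inverse(x, y)
        return float(lon), float(lat)

    old = [ll(zb, -18, 10), ll(zb, -30, 20), ll(zb, 5, -40), ll(zb, -38, -18)]
    new = [ll(vl, 25, 12), ll(vl, -15, 35), ll(vl, 44, -10), ll(vl, 10, 48)]
    unique = ll(vl, -45, -35)
    return {
        "zb_zb": [(lo, la, 1.0) for lo, la in old],
        "vl_vl": [(lo, la, 1.0) for lo, la in new],
        "zb_vl": [(*old[0], 0.3), (*old[2], 0.3), (*new[0], 0.2),
                  (*unique, 0.2)],
    }


def _default_growth_effects() -> dict[str, dict[str, float]]:
    # offsets on each logistic parameter; terms are brood3 (3-chick nest),
    # male, zb_vl (relocated parents) and their products
    return {
        "A": {"intercept": 850.0, "brood3": -60.0, "male": 40.0},
        "I": {"intercept": 12.0, "brood3": 0.8, "zb_vl": 0.5,
              "brood3:zb_vl": 0.7},
        "K": {"intercept": 0.18, "male": 0.012, "brood3:zb_vl": -0.03},
    }


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the study design."""

    seed: int = 0
    groups: tuple[str, ...] = ("zb_zb", "vl_vl", "zb_vl")
    n_birds_per_group: int | dict = dfield(
        default_factory=lambda: {"zb_zb": 29, "vl_vl": 8, "zb_vl": 8})
    colony_centers: dict = dfield(default_factory=lambda: dict(COLONY_CENTERS))
    colony_of_group: dict = dfield(default_factory=lambda: dict(COLONY_OF_GROUP))
    colony_halfwidth_m: float = 250.0
    foraging_sites: dict = dfield(default_factory=_default_sites)
    fix_interval: float = 180.0          # s
    flight_speed: float = 40.0           # km/h commuting speed
    dwell_time_mean: float = 2.0         # h at the foraging site
    dwell_jitter_km: float = 0.15        # sd of small-scale movement on site
    dwell_jitter_tau_h: float = 1.0 / 6.0
    trips_per_day: float = 2.0           # Poisson mean
    site_fidelity_alpha: float = 1.5     # Dirichlet concentration of
    # per-bird site preferences; smaller = stronger individual
    # specialisation, hence higher repeatability of daily distances
    bird_rate_sd: float = 0.3            # lognormal sd of per-bird trip rate
    bird_dwell_sd: float = 0.3           # lognormal sd of per-bird dwell mean
    n_days: int = 30
    daylight: tuple[float, float] = (5.0, 21.0)   # local departure window
    force_midnight: bool = False         # add one 23:30 departure per day
    gps_noise_sd_m: float = 15.0
    colony_jitter_m: float = 50.0
    local_utc_offset: float = 2.0        # CEST
    start_date: str = "2016-05-15"
    # growth experiment (new colony only: vl_vl vs zb_vl parents)
    growth_groups: tuple[str, ...] = ("vl_vl", "zb_vl")
    nests_per_group_brood: dict = dfield(default_factory=lambda: {
        ("vl_vl", 1): 31, ("vl_vl", 3): 37, ("zb_vl", 1): 21, ("zb_vl", 3): 18})
    growth_effects: dict = dfield(default_factory=_default_growth_effects)
    random_sd: dict = dfield(default_factory=lambda: {
        "year": 5.0, "parent": 15.0, "nest": 10.0, "chick": 10.0})
    residual_sd: float = 20.0            # g
    growth_ages: tuple[int, ...] = tuple(range(0, 31, 2))
    chick_death_prob_brood3: float = 0.25
    years: tuple[int, ...] = (2015, 2016, 2017)
    # adult morphometrics (tracked males)
    adult_mass_mean: dict = dfield(default_factory=lambda: {
        "zb_zb": 947.0, "vl_vl": 803.0, "zb_vl": 854.0})
    adult_mass_sd: dict = dfield(default_factory=lambda: {
        "zb_zb": 64.0, "vl_vl": 61.0, "zb_vl": 74.0})
    adult_n_males: dict = dfield(default_factory=lambda: {
        "zb_zb": 14, "vl_vl": 6, "zb_vl": 7})

    def __post_init__(self):
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.trips_per_day < 0:
            raise ValueError("trips_per_day must be >= 0")
        for g in self.groups:
            sites = self.foraging_sites.get(g)
            if not sites:
                raise ValueError(f"group {g!r} has no foraging sites")
            w = np.array([s[2] for s in sites], dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError(f"group {g!r} has invalid site weights")

    def n_birds(self, group: str) -> int:
        if isinstance(self.n_birds_per_group, dict):
            return int(self.n_birds_per_group[group])
        return int(self.n_birds_per_group)


@dataclass
class SyntheticDataset:
    """Simulated fixes plus the ground truth the tests check against."""

    fixes: pd.DataFrame
    colonies: dict[str, ColonyPolygon]
    truth_trips: pd.DataFrame
    birds: pd.DataFrame   # bird_id, group, colony, hatch_date


def _simulate_bird(cfg: SimulationConfig, rng, bird_id, group, proj,
                   t0_utc: pd.Timestamp):
    """One bird's fix stream in its colony-centred plane, plus truth trips."""
    sites = cfg.foraging_sites[group]
    sxy = np.array([proj.forward(lo, la) for lo, la, _ in sites])
    w = np.array([s[2] for s in sites], dtype=float)
    w = w / w.sum()
    if cfg.site_fidelity_alpha > 0 and len(w) > 1:
        # individual site preference: birds are consistent within
        # themselves but differ from each other
        w = rng.dirichlet(cfg.site_fidelity_alpha * len(w) * w)
        w = np.maximum(w, 1e-12)
        w = w / w.sum()
    dists = np.hypot(sxy[:, 0], sxy[:, 1])

    # per-bird behavioural consistency: trip rate and dwell time
    rate = cfg.trips_per_day * rng.lognormal(0.0, cfg.bird_rate_sd)
    dwell_mean = cfg.dwell_time_mean * rng.lognormal(0.0, cfg.bird_dwell_sd)

    # schedule trips day by day
    trips = []   # (t_dep, t_arr, t_ret, t_home, site_idx) in hours since t0
    t_busy = -np.inf
    for day in range(cfg.n_days):
        k = rng.poisson(rate)
        deps = np.sort(rng.uniform(*cfg.daylight, size=k)) + 24.0 * day
        if cfg.force_midnight:
            deps = np.append(deps, 24.0 * day + 23.5)
        for td in deps:
            if td < t_busy + 0.25:
                continue
            j = rng.choice(len(sites), p=w)
            t_fly = dists[j] / cfg.flight_speed
            dwell = rng.gamma(2.0, dwell_mean / 2.0)
            ta, tr = td + t_fly, td + t_fly + dwell
            th = tr + t_fly
            trips.append((td, ta, tr, th, j))
            t_busy = th

    # waypoint piecewise-linear path
    wp_t, wp_x, wp_y = [-1.0], [0.0], [0.0]
    for td, ta, tr, th, j in trips:
        wp_t += [td, ta, tr, th]
        wp_x += [0.0, sxy[j, 0], sxy[j, 0], 0.0]
        wp_y += [0.0, sxy[j, 1], sxy[j, 1], 0.0]
    wp_t.append(cfg.n_days * 24.0 + 1.0)
    wp_x.append(0.0)
    wp_y.append(0.0)

    t = np.arange(0.0, cfg.n_days * 24.0, cfg.fix_interval / 3600.0)
    x = np.interp(t, wp_t, wp_x)
    y = np.interp(t, wp_t, wp_y)

    # small-scale OU-like jitter while on the foraging site
    phi_step = np.exp(-(cfg.fix_interval / 3600.0) / cfg.dwell_jitter_tau_h)
    for td, ta, tr, th, j in trips:
        m = (t > ta) & (t < tr)
        nm = int(m.sum())
        if nm == 0:
            continue
        z = np.empty((nm, 2))
        z[0] = rng.normal(0, cfg.dwell_jitter_km, 2)
        innov = rng.normal(0, cfg.dwell_jitter_km * np.sqrt(1 - phi_step**2),
                           size=(nm - 1, 2))
        for i in range(1, nm):
            z[i] = phi_step * z[i - 1] + innov[i - 1]
        x[m] += z[:, 0]
        y[m] += z[:, 1]

    # jitter within the colony while in attendance (clipped to stay inside)
    at_colony = np.ones(len(t), dtype=bool)
    for td, ta, tr, th, j in trips:
        at_colony &= ~((t > td) & (t < th))
    lim = max(cfg.colony_halfwidth_m - 30.0 - cfg.gps_noise_sd_m * 4, 0.0) / 1000.0
    cj = np.clip(rng.normal(0, cfg.colony_jitter_m / 1000.0,
                            size=(int(at_colony.sum()), 2)), -lim, lim)
    x[at_colony] += cj[:, 0]
    y[at_colony] += cj[:, 1]

    # GPS noise
    if cfg.gps_noise_sd_m > 0:
        x += rng.normal(0, cfg.gps_noise_sd_m / 1000.0, len(t))
        y += rng.normal(0, cfg.gps_noise_sd_m / 1000.0, len(t))

    lon, lat = proj.inverse(x, y)
    ts = t0_utc + pd.to_timedelta(t, unit="h")
    fixes = pd.DataFrame({"bird_id": bird_id, "group": group,
                          "timestamp": ts, "lon": lon, "lat": lat})
    truth = pd.DataFrame(
        [{"bird_id": bird_id, "group": group,
          "start": t0_utc + pd.Timedelta(hours=td),
          "end": t0_utc + pd.Timedelta(hours=th),
          "site_lon": sites[j][0], "site_lat": sites[j][1],
          "site_dist_km": dists[j]}
         for td, ta, tr, th, j in trips])
    return fixes, truth


def simulate_tracks(cfg: SimulationConfig) -> SyntheticDataset:
    """Simulate GPS fix streams for every bird in every group."""
    colonies = {cid: square_colony(cid, center, cfg.colony_halfwidth_m)
                for cid, center in cfg.colony_centers.items()}
    start_local = pd.Timestamp(cfg.start_date)
    t0_utc = (start_local - pd.Timedelta(hours=cfg.local_utc_offset)
              ).tz_localize("UTC")

    all_fixes, all_truth, bird_rows = [], [], []
    for group in cfg.groups:
        cid = cfg.colony_of_group[group]
        proj = AzimuthalEquidistant(*cfg.colony_centers[cid])
        for b in range(cfg.n_birds(group)):
            bird_id = f"{group}_{b + 1:02d}"
            rng = _rng(cfg.seed, "tracks",
                       zlib.crc32(bird_id.encode()) % (2**31))
            fixes, truth = _simulate_bird(cfg, rng, bird_id, group, proj,
                                          t0_utc)
            all_fixes.append(fixes)
            if len(truth):
                all_truth.append(truth)
            hatch = start_local.date() + pd.Timedelta(days=int(rng.integers(0, 4)))
            bird_rows.append({"bird_id": bird_id, "group": group,
                              "colony": cid, "hatch_date": hatch})
    fixes = pd.concat(all_fixes, ignore_index=True)
    truth = (pd.concat(all_truth, ignore_index=True) if all_truth else
             pd.DataFrame(columns=["bird_id", "group", "start", "end",
                                   "site_lon", "site_lat", "site_dist_km"]))
    return SyntheticDataset(fixes=fixes, colonies=colonies,
                            truth_trips=truth,
                            birds=pd.DataFrame(bird_rows))


# ---------------------------------------------------------------------------
# Chick growth


def logistic_mass(t, A, I, K):
    """Logistic growth curve: mass (g) at age t days."""
    t = np.asarray(t, dtype=float)
    return A / (1.0 + np.exp(K * (I - t)))


def _param_value(effects: dict[str, float], brood3: bool, male: bool,
                 relocated: bool) -> float:
    on = {"brood3": brood3, "male": male, "zb_vl": relocated}
    val = effects.get("intercept", 0.0)
    for term, off in effects.items():
        if term == "intercept":
            continue
        if all(on[part] for part in term.split(":")):
            val += off
    return val


def simulate_growth(cfg: SimulationConfig):
    """Simulate the brood-size-manipulation growth experiment.

    Returns (records, truth) where records has one row per measurement
    (chick_id, nest_id, parent_id, year, sex, brood_size, origin,
    age_days, mass_g) and truth carries each chick's true (A, I, K) and
    the variance components used.
    """
    rng = _rng(cfg.seed, "growth")
    rows, truth_rows = [], []
    year_fx = {y: rng.normal(0, cfg.random_sd["year"]) for y in cfg.years}
    parent_fx: dict[str, float] = {}
    nest_counter = 0
    for origin in cfg.growth_groups:
        # a pool smaller than the nest count, so some pairs breed in
        # several years and the parent factor is not aliased with nest
        n_total = sum(cfg.nests_per_group_brood.get((origin, b), 0)
                      for b in (1, 3))
        pool = [f"par_{origin}_{i:03d}"
                for i in range(max(int(np.ceil(0.7 * n_total)), 1))]
        for brood in (1, 3):
            n_nests = cfg.nests_per_group_brood.get((origin, brood), 0)
            for _ in range(n_nests):
                nest_counter += 1
                nest_id = f"nest_{nest_counter:03d}"
                parent_id = pool[int(rng.integers(len(pool)))]
                year = int(rng.choice(cfg.years))
                if parent_id not in parent_fx:
                    parent_fx[parent_id] = rng.normal(0, cfg.random_sd["parent"])
                b_parent = parent_fx[parent_id]
                b_nest = rng.normal(0, cfg.random_sd["nest"])
                for c in range(brood):
                    chick_id = f"{nest_id}_c{c + 1}"
                    sex = "M" if rng.random() < 0.5 else "F"
                    male, reloc, b3 = sex == "M", origin == "zb_vl", brood == 3
                    A = _param_value(cfg.growth_effects["A"], b3, male, reloc)
                    I = _param_value(cfg.growth_effects["I"], b3, male, reloc)
                    K = _param_value(cfg.growth_effects["K"], b3, male, reloc)
                    b_chick = rng.normal(0, cfg.random_sd["chick"])
                    died = (b3 and rng.random() < cfg.chick_death_prob_brood3)
                    max_age = rng.uniform(0, 28) if died else 30.5
                    ages = [a for a in cfg.growth_ages if a <= max_age]
                    for a in ages:
                        mass = (logistic_mass(a, A, I, K)
                                + year_fx[year] + b_parent + b_nest + b_chick
                                + rng.normal(0, cfg.residual_sd))
                        rows.append({"chick_id": chick_id, "nest_id": nest_id,
                                     "parent_id": parent_id, "year": year,
                                     "sex": sex, "brood_size": brood,
                                     "origin": origin, "age_days": a,
                                     "mass_g": mass})
                    truth_rows.append({"chick_id": chick_id, "A": A, "I": I,
                                       "K": K, "died": died,
                                       "n_obs": len(ages)})
    records = pd.DataFrame(rows)
    truth = {"chicks": pd.DataFrame(truth_rows),
             "variance_components": {f"{k}_sd": v
                                     for k, v in cfg.random_sd.items()},
             "residual_sd": cfg.residual_sd,
             "effects": cfg.growth_effects}
    return records, truth


def simulate_adult_masses(cfg: SimulationConfig) -> pd.DataFrame:
    """Body masses of the tracked males, by origin group."""
    rng = _rng(cfg.seed, "adults")
    rows = []
    for group in cfg.groups:
        n = cfg.adult_n_males[group]
        masses = rng.normal(cfg.adult_mass_mean[group],
                            cfg.adult_mass_sd[group], size=n)
        for i, m in enumerate(masses):
            rows.append({"bird_id": f"{group}_m{i + 1:02d}", "origin": group,
                         "sex": "M", "mass_g": float(m)})
    return pd.DataFrame(rows)
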