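"""Monte-Carlo validation studies for the package's estimators.

Each function generates synthetic data with known truth, runs the
corresponding estimator end to end, and reports accuracy measures
(recovery error, coverage, type-I uniformity, fixture exactness). They
are used by the test suite and by scripts that summarise estimator
performance; every study is seed-controlled and self-contained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import growth, lmm
from .geo import AzimuthalEquidistant, square_colony
from .homerange import HomeRange, fit_ou, simulate_ou
from .overlap import bhattacharyya, gaussian_bc
from .repeatability import repeatability
from .simulate import logistic_mass
from .trips import daily_metrics, segment_trips


# ---------------------------------------------------------------------------
# Bhattacharyya: grid estimator vs Gaussian closed form


def _gaussian_homerange(mu, Sigma, cell, pad=14.0, name="g"):
    gx = np.arange(mu[0] - pad, mu[0] + pad, cell)
    gy = np.arange(mu[1] - pad, mu[1] + pad, cell)
    X, Y = np.meshgrid(gx, gy)
    d = stats.multivariate_normal(mu, Sigma).pdf(np.dstack([X, Y]))
    d /= d.sum() * cell * cell
    return HomeRange(name, gx, gy, d, np.asarray(Sigma), 1.0, proj=None)


def bhattacharyya_gaussian_study(cell_km: float = 0.25,
                                 separation_km: float = 10.0) -> dict:
    """Grid BC of two Gaussians 10 km apart vs the closed form exp(-D_B)."""
    S = np.diag([4.0, 4.0])
    a = _gaussian_homerange([0.0, 0.0], S, cell_km)
    b = _gaussian_homerange([separation_km, 0.0], S, cell_km, name="h")
    grid = bhattacharyya(a, b)
    closed = gaussian_bc([0, 0], S, [separation_km, 0], S)
    return {"bc_grid": grid, "bc_closed_form": closed,
            "abs_err": abs(grid - closed),
            "n_cells": a.density.size}


# ---------------------------------------------------------------------------
# OU timescale recovery


def ou_recovery_study(seed: int = 0, n_reps: int = 20, n_fixes: int = 2000,
                      tau_h: float = 0.5, fix_interval_h: float = 0.05,
                      sigma2_km2: float = 25.0) -> dict:
    """Median recovered tau over replicate simulated OU tracks."""
    t = np.arange(n_fixes) * fix_interval_h
    S = np.diag([sigma2_km2, sigma2_km2])
    taus = []
    for r in range(n_reps):
        rng = np.random.default_rng([seed % (2**31), 7, r])
        xy = simulate_ou([0, 0], S, tau_h, t, rng)
        taus.append(fit_ou(xy, times_h=t).tau_pos)
    med = float(np.median(taus))
    return {"tau_true_h": tau_h, "tau_median_h": med,
            "rel_err": abs(med - tau_h) / tau_h, "n_reps": n_reps,
            "n_fixes": n_fixes}


# ---------------------------------------------------------------------------
# ICC: REML vs ANOVA closed form, and bootstrap CI coverage


def icc_study(seed: int = 0, n_reps: int = 100, n_boot: int = 200,
              n_birds: int = 30, k: int = 20, tau2: float = 3.0,
              sigma2: float = 7.0) -> dict:
    """Balanced-design repeatability: oracle agreement and CI coverage."""
    R_true = tau2 / (tau2 + sigma2)
    birds = np.repeat(np.arange(n_birds), k)
    covered, diffs, Rs = 0, [], []
    for r in range(n_reps):
        rng = np.random.default_rng([seed % (2**31), 11, r])
        b = rng.normal(0, np.sqrt(tau2), n_birds)
        y = np.repeat(b, k) + rng.normal(0, np.sqrt(sigma2), n_birds * k)
        res = repeatability(y, birds, n_boot=n_boot, seed=int(rng.integers(2**31)))
        Rs.append(res.R)
        covered += (res.ci_low <= R_true <= res.ci_high)
        # closed-form balanced ICC from one-way ANOVA mean squares
        ym = y.reshape(n_birds, k).mean(axis=1)
        msb = k * ym.var(ddof=1)
        msw = ((y.reshape(n_birds, k) - ym[:, None]) ** 2).sum() / (
            n_birds * (k - 1))
        if msb > msw:   # ANOVA-consistent: interior estimate
            icc = (msb - msw) / (msb + (k - 1) * msw)
            diffs.append(abs(res.R - icc))
    return {"R_true": R_true, "R_median": float(np.median(Rs)),
            "coverage": covered / n_reps,
            "max_abs_diff_vs_anova": float(np.max(diffs)),
            "n_reps": n_reps, "n_boot": n_boot}


# ---------------------------------------------------------------------------
# Logistic growth recovery


def growth_recovery_study(seed: int = 0, n_chicks: int = 200,
                          A: float = 850.0, I: float = 12.0,
                          K: float = 0.18, residual_sd: float = 20.0) -> dict:
    """Per-chick logistic fits on noisy series measured every 2 days."""
    rng = np.random.default_rng([seed % (2**31), 13])
    ages = np.arange(0, 31, 2)
    relA, relK, ident = [], [], []
    n_conv = 0
    for i in range(n_chicks):
        m = logistic_mass(ages, A, I, K) + rng.normal(0, residual_sd,
                                                      len(ages))
        gp = growth.fit_logistic(ages, m, seed=i)
        if not gp.converged:
            continue
        n_conv += 1
        relA.append(abs(gp.A - A) / A)
        relK.append(abs(gp.K - K) / K)
        ident.append(abs(logistic_mass(gp.I, gp.A, gp.I, gp.K) - gp.A / 2))
    return {"A_median_rel_err": float(np.median(relA)),
            "K_median_rel_err": float(np.median(relK)),
            "halfmass_identity_max_err_g": float(np.max(ident)),
            "n_converged": n_conv, "n_chicks": n_chicks}


# ---------------------------------------------------------------------------
# Trip segmentation fixtures


def _fixture_traj(colony, legs, t0):
    proj = AzimuthalEquidistant(*colony.center)
    t0 = pd.Timestamp(t0)
    rows = []
    for minutes, x, y in legs:
        lon, lat = proj.inverse(np.array([x]), np.array([y]))
        rows.append({"bird_id": "fixture",
                     "timestamp": t0 + pd.Timedelta(minutes=minutes),
                     "lon": float(lon[0]), "lat": float(lat[0])})
    return pd.DataFrame(rows)


def _outback(dist_km, step_min, n_steps, t_start):
    legs = [(t_start + i * step_min, dist_km * i / n_steps, 0.0)
            for i in range(n_steps + 1)]
    legs += [(t_start + (n_steps + i) * step_min,
              dist_km * (n_steps - i) / n_steps, 0.0)
             for i in range(1, n_steps + 1)]
    return legs


def trip_fixture_study() -> dict:
    """Exactness checks on constructed noise-free trajectories.

    Three excursions, one failing both exclusion filters; one exact
    out-and-back loop within a single date; one loop forced across local
    midnight.
    """
    colony = square_colony("c", (3.5, 51.4), 250.0)

    legs = _outback(5.0, 3.0, 5, 0)                     # 30 min, 5 km
    legs += [(40 + m, 0.5 if m in (3, 6) else 0.0, 0.0)  # 9 min, 0.5 km
             for m in (0, 3, 6, 9)]
    legs += _outback(10.0, 3.0, 10, 60)                 # 60 min, 10 km
    traj = _fixture_traj(colony, legs, "2016-06-01T06:00:00+00:00")
    n_retained = len(segment_trips(traj, colony))

    loop = _fixture_traj(colony, _outback(20.0, 3.0, 10, 0),
                         "2016-06-01T06:00:00+00:00")
    tr = segment_trips(loop, colony)
    dm = daily_metrics(tr, colony)
    straight_day = float(dm["straightness"].iloc[0])

    midnight = _fixture_traj(colony, _outback(20.0, 6.0, 10, 0),
                             "2016-06-01T21:00:00+00:00")  # 23:00 local
    tr2 = segment_trips(midnight, colony)
    dm2 = daily_metrics(tr2, colony, local_utc_offset=2.0)
    straight_midnight = float(dm2["straightness"].max())

    return {"n_trips_retained": n_retained,
            "straightness_single_loop": straight_day,
            "straightness_midnight_max": straight_midnight,
            "n_midnight_dates": int(len(dm2))}


# ---------------------------------------------------------------------------
# Type-I control of the mixed-model group test


def type1_study(seed: int = 0, n_reps: int = 200, n_birds: int = 45,
                n_days: int = 30) -> dict:
    """Null p-value uniformity for the origin term across replicates.

    Three groups drawn from one distribution; birds vary but groups do
    not, so the origin term's p-values should be Uniform(0, 1).
    """
    groups = np.repeat(["a", "b", "c"], n_birds // 3)
    ps = []
    for r in range(n_reps):
        rng = np.random.default_rng([seed % (2**31), 17, r])
        bird_fx = rng.normal(0, 2.0, n_birds)
        df = pd.DataFrame({
            "bird_id": np.repeat(np.arange(n_birds), n_days),
            "group": np.repeat(groups, n_days),
            "chick_age_days": np.tile(np.arange(n_days), n_birds)})
        df["y"] = (np.repeat(bird_fx, n_days)
                   + rng.normal(0, 3.0, len(df)))
        fit = lmm.fit_lmm("y ~ group * chick_age_days", df,
                          random=("bird_id",))
        ps.append(lmm.wald_f(fit, "group")[3])
    ks = stats.kstest(ps, "uniform")
    return {"ks_p": float(ks.pvalue), "mean_p": float(np.mean(ps)),
            "frac_below_05": float(np.mean(np.asarray(ps) < 0.05)),
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# Overlap-network clustering fixture


def network_clustering_study(seed: int = 0, n_per_group: int = 3,
                             n_fixes: int = 700) -> dict:
    """Two disjoint-ground groups plus a mixed group in between.

    The mixed group's mean overlap with each resident group should lie
    between the residents' mutual overlap and their within-group
    overlap.
    """
    from .homerange import akde
    from .overlap import clustering_summary, pairwise_overlap

    rng = np.random.default_rng([seed % (2**31), 19])
    t = np.arange(n_fixes) * 0.05
    S = np.diag([16.0, 16.0])
    hrs, meta = {}, []
    for g, c in {"a": [0.0, 0.0], "b": [60.0, 0.0]}.items():
        for i in range(n_per_group):
            mu = np.asarray(c) + rng.normal(0, 2, 2)
            xy = simulate_ou(mu, S, 0.4, t, rng)
            f = fit_ou(xy, times_h=t, bird_id=f"{g}{i}")
            hrs[f.bird_id] = akde(f, cell_km=1.0)
            meta.append({"bird_id": f.bird_id, "group": g})
    for i in range(n_per_group):
        mu = np.array([30.0, 0.0]) + rng.normal(0, 2, 2)
        xy = simulate_ou(mu, np.diag([400.0, 30.0]), 0.4, t, rng)
        f = fit_ou(xy, times_h=t, bird_id=f"r{i}")
        hrs[f.bird_id] = akde(f, cell_km=1.0)
        meta.append({"bird_id": f.bird_id, "group": "r"})

    res = pairwise_overlap(hrs)
    summ = clustering_summary(res, pd.DataFrame(meta)).set_index("pair")
    within = {g: summ.loc[f"{g} | {g}", "mean_bc"] for g in ("a", "b")}
    between = summ.loc["a | b", "mean_bc"]
    mixed = {g: summ.loc[f"{g} | r", "mean_bc"] for g in ("a", "b")}
    intermediate = all(between < mixed[g] < max(within.values())
                       for g in ("a", "b"))
    return {"within_mean_bc": float(np.mean(list(within.values()))),
            "between_mean_bc": float(between),
            "mixed_to_a_bc": float(mixed["a"]),
            "mixed_to_b_bc": float(mixed["b"]),
            "relocated_intermediate": bool(intermediate)}
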