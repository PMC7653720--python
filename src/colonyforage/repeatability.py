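"""Repeatability (intraclass correlation) of daily foraging metrics.

R = tau2 / (tau2 + sigma2) from a Gaussian random-intercept model with
bird identity as the grouping factor and an intercept-only fixed part,
fitted by REML. The standard error comes from a parametric bootstrap
(resimulate from the fitted model, refit); the p-value from a likelihood
ratio test of tau2 = 0 against the boundary-corrected mixture
0.5*chi2_0 + 0.5*chi2_1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import lmm


@dataclass
class RepeatabilityResult:
    group: str
    metric: str
    R: float
    SE: float
    p_value: float
    ci_low: float
    ci_high: float
    tau2: float
    sigma2: float
    n_birds: int
    n_obs: int


def _icc_fit(values: np.ndarray, birds: np.ndarray) -> lmm.LMMFit:
    X = np.ones((len(values), 1))
    return lmm.fit_reml(values, X, factors={"bird": birds},
                        beta_names=["Intercept"])


def repeatability(values, birds, *, group: str = "", metric: str = "",
                  n_boot: int = 1000, seed: int = 0,
                  min_birds: int = 5, min_obs_per_bird: int = 2
                  ) -> RepeatabilityResult:
    """Estimate R for one metric within one group of birds.

    ``values`` are day-level observations, ``birds`` the matching bird
    identities (one row per bird-day, unaggregated).
    """
    values = np.asarray(values, dtype=float)
    birds = np.asarray(birds)
    ok = np.isfinite(values)
    values, birds = values[ok], birds[ok]
    uniq, counts = np.unique(birds, return_counts=True)
    if len(uniq) < min_birds:
        raise ValueError(f"need >= {min_birds} birds (got {len(uniq)})")
    if (counts < min_obs_per_bird).all():
        raise ValueError(f"need >= {min_obs_per_bird} observations per bird")

    fit = _icc_fit(values, birds)
    tau2 = fit.tau2["bird"]
    sigma2 = fit.sigma2
    R = tau2 / (tau2 + sigma2)

    # LRT of tau2 = 0 against the 0.5*chi2_0 + 0.5*chi2_1 mixture
    if tau2 <= 0:
        R, p = 0.0, 1.0
    else:
        dev_null = fit._work.deviance(np.zeros(1))
        lrt = max(dev_null - (-2.0 * fit.reml_loglik), 0.0)
        p = 0.5 * stats.chi2.sf(lrt, 1) if lrt > 0 else 1.0

    # parametric bootstrap from the fitted model, same design
    rng = np.random.default_rng(seed)
    idx = pd.factorize(birds)[0]
    nb = len(uniq)
    mu = float(fit.beta[0])
    Rs = np.empty(n_boot)
    for b in range(n_boot):
        u = rng.normal(0, np.sqrt(max(tau2, 0.0)), nb)
        yb = mu + u[idx] + rng.normal(0, np.sqrt(sigma2), len(values))
        fb = _icc_fit(yb, birds)
        t2, s2 = fb.tau2["bird"], fb.sigma2
        Rs[b] = t2 / (t2 + s2)
    se = float(np.std(Rs, ddof=1)) if n_boot > 1 else np.nan
    lo, hi = (np.percentile(Rs, [2.5, 97.5]) if n_boot > 1
              else (np.nan, np.nan))
    return RepeatabilityResult(group=group, metric=metric, R=float(R),
                               SE=se, p_value=float(p),
                               ci_low=float(lo), ci_high=float(hi),
                               tau2=float(tau2), sigma2=float(sigma2),
                               n_birds=nb, n_obs=len(values))


def repeatability_table(metrics: pd.DataFrame,
                        metric_cols: tuple[str, ...] = ("max_distance_km",
                                                        "total_distance_km",
                                                        "duration_h"),
                        group_col: str = "group",
                        n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-group, per-metric repeatability of the daily foraging metrics."""
    rows = []
    for g, sub in metrics.groupby(group_col, sort=True):
        for i, m in enumerate(metric_cols):
            r = repeatability(sub[m], sub["bird_id"], group=str(g), metric=m,
                              n_boot=n_boot, seed=seed + 31 * i)
            rows.append({"group": r.group, "metric": r.metric, "R": r.R,
                         "SE": r.SE, "p_value": r.p_value,
                         "n_birds": r.n_birds, "n_obs": r.n_obs})
    return pd.DataFrame(rows)
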