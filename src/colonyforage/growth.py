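"""Logistic chick-growth curves and growth-parameter models.

Each chick's mass series (measured every 2-3 days to day 30) is fitted by
unweighted nonlinear least squares to W_t = A / (1 + exp(K (I - t))),
where A is the asymptotic mass (g), K the growth rate constant (1/day)
and I the inflection age (days, the age at which mass = A/2). Chicks
whose series cannot be fitted (died young, too few points, boundary or
non-converged fits) are excluded downstream. Fitted parameters are then
analysed with a full-factorial mixed model in brood size, sex and
parental origin, with year, parent, nest and chick as independent random
intercepts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import lmm
from .simulate import logistic_mass

log = logging.getLogger(__name__)

MIN_POINTS = 4


@dataclass
class GrowthParams:
    chick_id: str
    A: float
    I: float
    K: float
    rss: float
    converged: bool


def fit_logistic(ages, masses, chick_id: str = "",
                 n_starts: int = 3, seed: int = 0) -> GrowthParams:
    """Least-squares logistic fit for one chick.

    Starting values: A0 = 1.05 * max(mass), I0 = age at the mass closest
    to A0/2, K0 = 0.2/day, plus jittered restarts (noisy short series make
    the problem multimodal). A fit is converged only if the optimiser
    reports success and the parameters are interior (A > 0, K > 0,
    0 < I < 30).
    """
    ages = np.asarray(ages, dtype=float)
    masses = np.asarray(masses, dtype=float)
    order = np.argsort(ages)
    ages, masses = ages[order], masses[order]
    if len(ages) < MIN_POINTS:
        return GrowthParams(chick_id, np.nan, np.nan, np.nan, np.nan, False)

    A0 = 1.05 * masses.max()
    I0 = float(ages[np.argmin(np.abs(masses - A0 / 2.0))])
    K0 = 0.2

    def resid(theta):
        A, I, K = theta
        return logistic_mass(ages, A, I, K) - masses

    rng = np.random.default_rng(seed)
    best = None
    starts = [(A0, I0, K0)]
    for _ in range(n_starts - 1):
        starts.append((A0 * rng.uniform(0.8, 1.2),
                       np.clip(I0 + rng.normal(0, 3), 1, 29),
                       K0 * rng.uniform(0.5, 2.0)))
    for s in starts:
        try:
            res = optimize.least_squares(resid, s, method="lm",
                                         gtol=1e-8, xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return GrowthParams(chick_id, np.nan, np.nan, np.nan, np.nan, False)
    A, I, K = best.x
    interior = (A > 0) and (K > 0) and (0 < I < 30)
    conv = bool(best.success) and interior
    return GrowthParams(chick_id, float(A), float(I), float(K),
                        float(2 * best.cost), conv)


def fit_all_chicks(records: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Fit every chick; returns one row per chick with its covariates."""
    rows = []
    covar_cols = [c for c in ("nest_id", "parent_id", "year", "sex",
                              "brood_size", "origin") if c in records.columns]
    for chick_id, sub in records.groupby("chick_id", sort=True):
        gp = fit_logistic(sub["age_days"], sub["mass_g"], str(chick_id),
                          seed=seed)
        row = {"chick_id": str(chick_id), "A": gp.A, "I": gp.I, "K": gp.K,
               "rss": gp.rss, "converged": gp.converged,
               "n_obs": len(sub)}
        row.update(sub.iloc[0][covar_cols].to_dict())
        rows.append(row)
    out = pd.DataFrame(rows)
    n_bad = int((~out["converged"]).sum())
    if n_bad:
        log.info("excluded %d of %d chicks with non-converged or too-short "
                 "growth series", n_bad, len(out))
    return out


GROWTH_FORMULA = "{param} ~ C(brood_size) * sex * origin"
GROWTH_RANDOM = ("year", "parent_id", "nest_id", "chick_id")


def analyse_growth(params: pd.DataFrame,
                   random: tuple[str, ...] = GROWTH_RANDOM) -> dict:
    """Mixed-model term tables (F, df, p) for A, I and K.

    Uses only converged fits. The full factorial fixed design includes
    all pairwise and the three-way interaction of brood size, sex and
    parental origin. Chick identity, with one fitted value per chick, is
    confounded with the residual and is reported at the boundary.
    """
    ok = params[params["converged"]].reset_index(drop=True)
    random = tuple(r for r in random if r in ok.columns)
    out = {}
    for p in ("A", "I", "K"):
        fit = lmm.fit_lmm(GROWTH_FORMULA.format(param=p), ok, random=random)
        out[p] = {"fit": fit, "terms": lmm.term_table(fit)}
    return out
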