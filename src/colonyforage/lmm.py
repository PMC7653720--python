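"""Variance-component Gaussian mixed models fitted by REML.

The model is  y = X beta + sum_k Z_k b_k + e,  with independent random
intercepts b_k ~ N(0, tau2_k I) for each grouping factor k (e.g. year,
parent, nest, chick) and e ~ N(0, sigma2 I). The marginal covariance
V = sum_k tau2_k Z_k Z_k' + sigma2 I is handled through its Woodbury
factorisation, so each REML evaluation costs O(q^3) in the total number
of random levels q rather than O(n^3) — all problems in scope are
desk-scale (n up to a few thousand, q up to a few hundred).

REML profiles out both the fixed effects and the residual variance; the
optimiser works on the log variance ratios gamma_k = tau2_k / sigma2
(multi-start Nelder--Mead, with explicit boundary probes at gamma_k = 0).
Denominator degrees of freedom for Wald F tests use the Satterthwaite
approximation (delta method on the variance-component covariance obtained
from the numerical REML Hessian). Tukey HSD contrasts are built on an
emmeans-style reference grid and referred to the studentized range.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import linalg, optimize, stats

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


class LMMError(Exception):
    pass


class AliasingError(LMMError):
    """Fixed design is rank deficient (a term is aliased)."""


class ConvergenceError(LMMError):
    def __init__(self, msg, best=None):
        super().__init__(msg)
        self.best = best


@dataclass
class LMMFit:
    """A fitted variance-component mixed model."""

    beta: np.ndarray
    beta_names: list[str]
    sigma2: float
    tau2: dict[str, float]
    reml_loglik: float
    vcov_beta: np.ndarray
    n: int
    p: int
    q: int
    converged: bool
    design_info: object | None = None
    data: pd.DataFrame | None = None
    _work: object | None = field(default=None, repr=False)
    _satt_cache: dict = field(default_factory=dict, repr=False)

    @property
    def fixed_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov_beta))
        return pd.DataFrame({"estimate": self.beta, "se": se},
                            index=self.beta_names)


class _REMLWork:
    """Precomputed cross-products for fast repeated REML evaluation."""

    def __init__(self, y, X, factors: dict[str, np.ndarray]):
        y = np.asarray(y, dtype=float).ravel()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        if len(y) != n:
            raise LMMError("response and design row counts differ")
        rank = np.linalg.matrix_rank(X)
        if rank < p:
            # name the aliased columns via pivoted QR
            _, _, piv = linalg.qr(X, pivoting=True, mode="economic")
            bad = sorted(piv[rank:])
            raise AliasingError(f"fixed design is rank deficient; aliased "
                                f"column indices: {bad}")
        if n <= p:
            raise LMMError(f"need n > p (n={n}, p={p})")

        self.y, self.X, self.n, self.p = y, X, n, p
        self.factor_names = list(factors)
        self.confounded: list[str] = []
        Zs = []
        self.col_of_factor = []  # factor index for each Z column
        self.q_k = []
        for j, (name, codes) in enumerate(factors.items()):
            codes = np.asarray(codes)
            levels, idx = np.unique(codes, return_inverse=True)
            qk = len(levels)
            if qk < 2:
                raise LMMError(f"random factor {name!r} has < 2 levels")
            if qk == n:
                # one level per observation: indistinguishable from residual
                log.warning("random factor %r has one level per observation; "
                            "confounded with the residual, component reported "
                            "at the boundary (0)", name)
                self.confounded.append(name)
            Zk = np.zeros((n, qk))
            Zk[np.arange(n), idx] = 1.0
            Zs.append(Zk)
            self.col_of_factor.extend([j] * qk)
            self.q_k.append(qk)
        self.col_of_factor = np.asarray(self.col_of_factor, dtype=int)
        self.K = len(Zs)
        self.q = int(sum(self.q_k))
        Z = np.hstack(Zs) if Zs else np.zeros((n, 0))
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    # -- profiled REML deviance -------------------------------------------

    def _pieces(self, gamma: np.ndarray):
        """Return (logdetW, XtWiX, XtWiy, ytWiy) for W = I + Z G Z'."""
        n, p = self.n, self.p
        if self.K == 0 or np.all(gamma <= 0):
            return 0.0, self.XtX, self.Xty, self.yty
        g_col = gamma[self.col_of_factor]
        live = g_col > 0           # columns of factors at the boundary drop out
        s = np.sqrt(g_col[live])
        A = np.eye(int(live.sum())) + (
            s[:, None] * self.ZtZ[np.ix_(live, live)] * s[None, :])
        cA, low = linalg.cho_factor(A, lower=True)
        logdetW = 2.0 * float(np.sum(np.log(np.diag(cA))))
        SX = s[:, None] * self.ZtX[live]
        Sy = s * self.Zty[live]
        AiSX = linalg.cho_solve((cA, low), SX)
        AiSy = linalg.cho_solve((cA, low), Sy)
        XtWiX = self.XtX - SX.T @ AiSX
        XtWiy = self.Xty - SX.T @ AiSy
        ytWiy = self.yty - float(Sy @ AiSy)
        return logdetW, XtWiX, XtWiy, ytWiy

    def deviance(self, gamma: np.ndarray) -> float:
        """Profiled -2 * REML log-likelihood at variance ratios gamma."""
        n, p = self.n, self.p
        logdetW, XtWiX, XtWiy, ytWiy = self._pieces(gamma)
        try:
            c = linalg.cho_factor(XtWiX)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(c, XtWiy)
        rWr = max(ytWiy - float(beta @ XtWiy), 1e-300)
        sigma2 = rWr / (n - p)
        logdet_XtWiX = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        return ((n - p) * (_LOG2PI + 1.0 + np.log(sigma2))
                + logdetW + logdet_XtWiX)

    def deviance_theta(self, tau2: np.ndarray, sigma2: float) -> float:
        """-2 REML log-likelihood at explicit (tau2, sigma2) (unprofiled)."""
        n, p = self.n, self.p
        gamma = np.asarray(tau2, dtype=float) / sigma2
        logdetW, XtWiX, XtWiy, ytWiy = self._pieces(gamma)
        c = linalg.cho_factor(XtWiX)
        beta = linalg.cho_solve(c, XtWiy)
        rWr = ytWiy - float(beta @ XtWiy)
        logdet_XtWiX = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        return ((n - p) * (_LOG2PI + np.log(sigma2))
                + logdetW + logdet_XtWiX + rWr / sigma2)

    def solve_at(self, gamma: np.ndarray):
        """beta, sigma2, vcov_beta, loglik at the given variance ratios."""
        n, p = self.n, self.p
        logdetW, XtWiX, XtWiy, ytWiy = self._pieces(gamma)
        c = linalg.cho_factor(XtWiX)
        beta = linalg.cho_solve(c, XtWiy)
        rWr = max(ytWiy - float(beta @ XtWiy), 1e-300)
        sigma2 = rWr / (n - p)
        vcov = sigma2 * linalg.cho_solve(c, np.eye(p))
        dev = self.deviance(gamma)
        return beta, sigma2, vcov, -0.5 * dev


def _optimise_gamma(work: _REMLWork, tol: float = 1e-8,
                    max_restarts: int = 4):
    """Minimise the profiled REML deviance over log variance ratios."""
    K = work.K
    free = [k for k, name in enumerate(work.factor_names)
            if name not in work.confounded]
    gamma = np.zeros(K)
    if not free:
        return gamma, work.deviance(gamma), True

    def dev_free(u):
        g = gamma.copy()
        g[free] = np.exp(np.clip(u, -40, 40))
        return work.deviance(g)

    if len(free) == 1:
        # one variance ratio: bracket on a coarse grid, refine by Brent,
        # probe the boundary explicitly
        grid = np.linspace(-12.0, 8.0, 21)
        vals = [dev_free(np.array([u])) for u in grid]
        u0 = grid[int(np.argmin(vals))]
        res = optimize.minimize_scalar(
            lambda u: dev_free(np.array([u])),
            bounds=(u0 - 1.5, u0 + 1.5), method="bounded",
            options={"xatol": 1e-8})
        g_hat = gamma.copy()
        g_hat[free[0]] = np.exp(res.x)
        d_hat = res.fun
        d0 = work.deviance(gamma)   # gamma_k = 0
        if d0 <= d_hat or g_hat[free[0]] < 1e-10:
            return gamma, d0, True
        return g_hat, d_hat, True

    starts = [np.zeros(len(free)),
              np.full(len(free), -3.0),
              np.full(len(free), 2.0),
              np.linspace(-2, 2, len(free))]
    best_u, best_dev, any_ok = None, np.inf, False
    for u0 in starts[:max_restarts]:
        res = optimize.minimize(dev_free, u0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": tol,
                                         "maxiter": 2000 * max(1, len(free))})
        if res.fun < best_dev:
            best_u, best_dev = res.x, res.fun
            any_ok = any_ok or res.success
    if best_u is None:
        raise ConvergenceError("REML optimiser produced no candidate")

    g_hat = gamma.copy()
    g_hat[free] = np.exp(np.clip(best_u, -40, 40))
    # boundary probes: snap tiny components to exactly 0, refit the rest
    candidates = [(g_hat, best_dev)]
    zeroish = [k for k in free if g_hat[k] < 1e-7]
    for subset in ([zeroish] if zeroish else []) + [[k] for k in free] + [free]:
        g0 = g_hat.copy()
        g0[subset] = 0.0
        rest = [k for k in free if k not in subset]
        if rest:
            def dev_rest(u, rest=rest, g0=g0):
                g = g0.copy()
                g[rest] = np.exp(np.clip(u, -40, 40))
                return work.deviance(g)
            r = optimize.minimize(
                dev_rest, np.log(np.maximum(g_hat[rest], 1e-4)),
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": tol,
                         "maxiter": 2000 * len(rest)})
            gg = g0.copy()
            gg[rest] = np.exp(np.clip(r.x, -40, 40))
            candidates.append((gg, r.fun))
        else:
            candidates.append((g0, work.deviance(g0)))
    g_best, d_best = min(candidates, key=lambda t: t[1])
    if not any_ok and not np.isfinite(d_best):
        raise ConvergenceError("REML did not converge after restarts",
                               best=(g_best, d_best))
    return g_best, d_best, True


def fit_reml(y, X, factors: dict | None = None, *,
             beta_names: list[str] | None = None,
             design_info=None, data: pd.DataFrame | None = None,
             tol: float = 1e-8) -> LMMFit:
    """Fit the variance-component model by REML.

    Parameters
    ----------
    y, X : response vector and fixed-effects design matrix.
    factors : mapping of factor name -> per-observation level codes; each
        contributes an independent random intercept.
    """
    factors = factors or {}
    work = _REMLWork(y, X, factors)
    gamma, dev, ok = _optimise_gamma(work, tol=tol)
    beta, sigma2, vcov, loglik = work.solve_at(gamma)
    tau2 = {name: float(gamma[k] * sigma2)
            for k, name in enumerate(work.factor_names)}
    names = beta_names or [f"x{i}" for i in range(work.p)]
    return LMMFit(beta=beta, beta_names=list(names), sigma2=float(sigma2),
                  tau2=tau2, reml_loglik=float(loglik), vcov_beta=vcov,
                  n=work.n, p=work.p, q=work.q, converged=bool(ok),
                  design_info=design_info, data=data, _work=work)


def fit_lmm(formula: str, data: pd.DataFrame,
            random: tuple[str, ...] = (), **kw) -> LMMFit:
    """Formula front end: e.g. ``fit_lmm("K ~ brood_size * origin * sex",
    df, random=("year", "parent_id", "nest_id", "chick_id"))``."""
    data = data.reset_index(drop=True)
    ymat, Xmat = patsy.dmatrices(formula, data, return_type="dataframe",
                                 NA_action="raise")
    factors = {r: data[r].to_numpy() for r in random}
    return fit_reml(ymat.to_numpy().ravel(), Xmat.to_numpy(),
                    factors=factors, beta_names=list(Xmat.columns),
                    design_info=Xmat.design_info, data=data, **kw)


# ---------------------------------------------------------------------------
# Satterthwaite machinery


def _theta_cov(fit: LMMFit):
    """Covariance of the interior variance parameters (tau2_k>0, sigma2)
    from the numerical Hessian of the REML deviance; None if not PD."""
    work = fit._work
    names = [k for k in work.factor_names if fit.tau2[k] > 0]
    theta = np.array([fit.tau2[k] for k in names] + [fit.sigma2])

    def dev(th):
        tau2 = np.zeros(work.K)
        for i, nm in enumerate(names):
            tau2[work.factor_names.index(nm)] = th[i]
        return work.deviance_theta(tau2, th[-1])

    m = len(theta)
    H = np.empty((m, m))
    h = 1e-4 * np.maximum(np.abs(theta), 1e-3 * fit.sigma2)
    f0 = dev(theta)
    for i in range(m):
        for j in range(i, m):
            ti = theta.copy()
            if i == j:
                ti[i] += h[i]; fp = dev(ti)
                ti = theta.copy(); ti[i] -= h[i]; fm = dev(ti)
                H[i, i] = (fp - 2 * f0 + fm) / h[i] ** 2
            else:
                tpp = theta.copy(); tpp[[i, j]] += [h[i], h[j]]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = ((dev(tpp) - dev(tpm) - dev(tmp) + dev(tmm))
                                     / (4 * h[i] * h[j]))
    try:
        Acov = 2.0 * linalg.inv(H)
        if not np.all(np.linalg.eigvalsh((Acov + Acov.T) / 2) > 0):
            return None, names
    except linalg.LinAlgError:
        return None, names
    return Acov, names


def _contrast_var_grad(fit: LMMFit, L: np.ndarray, names):
    """f(theta) = L' C(theta) L and its finite-difference gradient."""
    work = fit._work
    theta = np.array([fit.tau2[k] for k in names] + [fit.sigma2])

    def fval(th):
        tau2 = np.zeros(work.K)
        for i, nm in enumerate(names):
            tau2[work.factor_names.index(nm)] = th[i]
        gamma = tau2 / th[-1]
        _, XtWiX, _, _ = work._pieces(gamma)
        C = th[-1] * linalg.inv(XtWiX)
        return float(L @ C @ L)

    f0 = fval(theta)
    g = np.empty(len(theta))
    h = 1e-4 * np.maximum(np.abs(theta), 1e-3 * fit.sigma2)
    for i in range(len(theta)):
        tp = theta.copy(); tp[i] += h[i]
        tm = theta.copy(); tm[i] = max(tm[i] - h[i], 1e-12)
        g[i] = (fval(tp) - fval(tm)) / (tp[i] - tm[i])
    return f0, g


def satterthwaite_df(fit: LMMFit, L: np.ndarray,
                     _cache: dict | None = None) -> float:
    """Satterthwaite denominator df for the scalar contrast L' beta."""
    if _cache is None:
        _cache = fit._satt_cache
    if "Acov" in _cache:
        Acov, names = _cache["Acov"], _cache["names"]
    else:
        Acov, names = _theta_cov(fit)
        _cache["Acov"], _cache["names"] = Acov, names
    if Acov is None:
        log.warning("REML Hessian not positive definite; "
                    "falling back to residual df n - p")
        return float(fit.n - fit.p)
    f0, g = _contrast_var_grad(fit, L, names)
    denom = float(g @ Acov @ g)
    if denom <= 0 or f0 <= 0:
        return float(fit.n - fit.p)
    return float(np.clip(2.0 * f0 ** 2 / denom, 1.0, 1e7))


def wald_f(fit: LMMFit, term: str):
    """Wald F test of a fixed term with Satterthwaite denominator df.

    Returns (F, df_num, df_den, p).
    """
    if fit.design_info is None:
        raise LMMError("fit carries no design info; use fit_lmm()")
    slices = fit.design_info.term_name_slices
    if term not in slices:
        raise LMMError(f"term {term!r} not in design "
                       f"({list(slices)})")
    sl = slices[term]
    idx = np.arange(fit.p)[sl]
    if idx.size == 0:
        raise AliasingError(f"term {term!r} contributes no columns "
                            "(aliased or single-level factor)")
    b = fit.beta[idx]
    Vb = fit.vcov_beta[np.ix_(idx, idx)]
    qt = idx.size
    F = float(b @ linalg.solve(Vb, b, assume_a="pos")) / qt

    # per-eigencomponent Satterthwaite df, combined as in multi-df Wald tests
    cache = fit._satt_cache
    evals, evecs = linalg.eigh(Vb)
    dfs = []
    for m in range(qt):
        Lfull = np.zeros(fit.p)
        Lfull[idx] = evecs[:, m]
        dfs.append(satterthwaite_df(fit, Lfull, _cache=cache))
    dfs = np.asarray(dfs)
    good = dfs > 2
    if good.any():
        E = float(np.sum(dfs[good] / (dfs[good] - 2)))
        df_den = 2 * E / (E - qt) if E > qt else float(fit.n - fit.p)
    else:
        df_den = float(fit.n - fit.p)
    p = float(stats.f.sf(F, qt, df_den))
    return F, qt, df_den, p


def term_table(fit: LMMFit, terms: list[str] | None = None) -> pd.DataFrame:
    """F / df / p table for every non-intercept fixed term."""
    if terms is None:
        terms = [t for t in fit.design_info.term_name_slices
                 if t != "Intercept"]
    rows = []
    for t in terms:
        F, dfn, dfd, p = wald_f(fit, t)
        rows.append({"term": t, "F": F, "df_num": dfn, "df_den": dfd, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Tukey HSD pairwise contrasts on a reference grid


def _reference_rows(fit: LMMFit, factor: str):
    """emmeans-style rows of the fixed design, one per level of `factor`:
    other categoricals averaged over their levels, numerics at their mean."""
    di = fit.design_info
    data = fit.data
    cat_vars, num_vars = [], []
    for f, info in di.factor_infos.items():
        name = f.name()
        if info.type == "categorical":
            cat_vars.append(name)
        else:
            num_vars.append(name)
    if factor not in cat_vars:
        # fall back: treat any column of `data` as categorical if requested
        if factor not in data.columns:
            raise LMMError(f"factor {factor!r} not found")
        cat_vars.append(factor)
    levels = list(pd.unique(data[factor]))
    others = [c for c in cat_vars if c != factor]
    rows, row_level = [], []
    other_levels = [list(pd.unique(data[c])) for c in others]
    for lev in levels:
        combos = list(itertools.product(*other_levels)) or [()]
        grid = pd.DataFrame([{factor: lev,
                              **dict(zip(others, combo)),
                              **{v: data[v].mean() for v in num_vars
                                 if v != factor}}
                             for combo in combos])
        (M,) = patsy.build_design_matrices([di], grid)
        rows.append(np.asarray(M).mean(axis=0))
        row_level.append(lev)
    return row_level, np.asarray(rows)


def tukey_pairwise(fit: LMMFit, factor: str,
                   df_policy: str = "satterthwaite") -> pd.DataFrame:
    """All pairwise contrasts between levels of `factor`, Tukey-adjusted.

    Adjusted p-values come from the studentized range with k levels; when
    the denominator df exceeds 200 the z (infinite-df) reference is used.
    """
    levels, M = _reference_rows(fit, factor)
    k = len(levels)
    cache = fit._satt_cache
    rows = []
    for a, b in itertools.combinations(range(k), 2):
        L = M[a] - M[b]
        est = float(L @ fit.beta)
        se = float(np.sqrt(L @ fit.vcov_beta @ L))
        if fit._work.K == 0 or df_policy == "residual":
            df = float(fit.n - fit.p)
        else:
            df = satterthwaite_df(fit, L, _cache=cache)
        tstat = est / se if se > 0 else np.nan
        use_df = 1e6 if df > 200 else df   # z reference for large df
        padj = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0),
                                                k, use_df)) if k > 1 else 1.0
        rows.append({"contrast": f"{levels[a]} - {levels[b]}",
                     "estimate": est, "se": se, "stat": tstat,
                     "df": df, "p_adj": min(padj, 1.0)})
    return pd.DataFrame(rows)


def group_means(fit: LMMFit, factor: str) -> pd.DataFrame:
    """Model-based marginal means +- SE per level of `factor`."""
    levels, M = _reference_rows(fit, factor)
    est = M @ fit.beta
    se = np.sqrt(np.einsum("ip,pq,iq->i", M, fit.vcov_beta, M))
    return pd.DataFrame({"level": levels, "mean": est, "se": se})
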