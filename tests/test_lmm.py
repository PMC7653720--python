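import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colonyforage import lmm


def balanced_oneway(rng, n_groups=30, k=20, tau2=4.0, sigma2=9.0, mu=5.0):
    b = rng.normal(0, np.sqrt(tau2), n_groups)
    y = mu + np.repeat(b, k) + rng.normal(0, np.sqrt(sigma2), n_groups * k)
    g = np.repeat(np.arange(n_groups), k)
    return y, g


def anova_components(y, g):
    """Method-of-moments one-way variance components (balanced)."""
    df = pd.DataFrame({"y": y, "g": g})
    k = df.groupby("g").size().iloc[0]
    means = df.groupby("g")["y"].mean()
    msb = k * means.var(ddof=1)
    msw = ((df["y"] - means[df["g"]].to_numpy()) ** 2).sum() / (
        len(df) - len(means))
    return (msb - msw) / k, msw


class TestFitREML:
    def test_no_random_factors_reproduces_ols_exactly(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = X @ [1.0, 2.0, -1.0] + rng.normal(0, 1, 40)
        fit = lmm.fit_reml(y, X)
        beta_ols, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-12)
        assert fit.sigma2 == pytest.approx(float(res[0]) / (40 - 3),
                                           rel=1e-12)

    def test_balanced_oneway_matches_anova_closed_form(self):
        rng = np.random.default_rng(1)
        y, g = balanced_oneway(rng)
        fit = lmm.fit_reml(y, np.ones((len(y), 1)), {"g": g})
        tau_a, sig_a = anova_components(y, g)
        assert fit.tau2["g"] == pytest.approx(tau_a, abs=1e-6)
        assert fit.sigma2 == pytest.approx(sig_a, abs=1e-6)

    def test_pure_noise_estimates_boundary_tau(self):
        rng = np.random.default_rng(2)
        taus = []
        for r in range(9):
            y, g = balanced_oneway(rng, n_groups=20, k=10, tau2=0.0,
                                   sigma2=4.0)
            fit = lmm.fit_reml(y, np.ones((len(y), 1)), {"g": g})
            taus.append(fit.tau2["g"] / fit.sigma2)
        assert np.median(taus) <= 1e-6

    def test_variance_recovery_crossed_factors(self):
        # two crossed factors recovered within broad Monte Carlo bounds
        rng = np.random.default_rng(3)
        est = []
        for r in range(10):
            a = rng.normal(0, 2.0, 15)
            b = rng.normal(0, 1.0, 12)
            ia = rng.integers(0, 15, 600)
            ib = rng.integers(0, 12, 600)
            y = 3 + a[ia] + b[ib] + rng.normal(0, 1.5, 600)
            fit = lmm.fit_reml(y, np.ones((600, 1)), {"a": ia, "b": ib})
            est.append([fit.tau2["a"], fit.tau2["b"], fit.sigma2])
        med = np.median(est, axis=0)
        assert med == pytest.approx([4.0, 1.0, 2.25], rel=0.15)

    def test_dense_and_masked_paths_agree(self):
        # deviance at the optimum is identical whether the boundary factor
        # columns are carried along or dropped
        rng = np.random.default_rng(4)
        y, g = balanced_oneway(rng, n_groups=10, k=8)
        work = lmm._REMLWork(y, np.ones((80, 1)),
                             {"g": g, "noise": rng.integers(0, 5, 80)})
        d1 = work.deviance(np.array([0.5, 0.0]))
        work1 = lmm._REMLWork(y, np.ones((80, 1)), {"g": g})
        d2 = work1.deviance(np.array([0.5]))
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_reparameterisation_leaves_variances_invariant(self):
        rng = np.random.default_rng(5)
        y, g = balanced_oneway(rng, n_groups=12, k=6)
        X = np.column_stack([np.ones(len(y)), rng.normal(size=len(y))])
        T = np.array([[2.0, 0.3], [0.0, -1.5]])   # invertible
        f1 = lmm.fit_reml(y, X, {"g": g})
        f2 = lmm.fit_reml(y, X @ T, {"g": g})
        assert f1.sigma2 == pytest.approx(f2.sigma2, rel=1e-5)
        assert f1.tau2["g"] == pytest.approx(f2.tau2["g"], rel=1e-4, abs=1e-8)
        np.testing.assert_allclose(f1.beta, T @ f2.beta, rtol=1e-5)

    def test_rank_deficient_design_raises_aliasing_error(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        X = np.column_stack([np.ones(30), x, 2 * x])
        with pytest.raises(lmm.AliasingError):
            lmm.fit_reml(rng.normal(size=30), X)

    def test_confounded_factor_reported_at_boundary(self):
        rng = np.random.default_rng(7)
        y, g = balanced_oneway(rng, n_groups=10, k=4)
        fit = lmm.fit_reml(y, np.ones((40, 1)),
                           {"g": g, "obs": np.arange(40)})
        assert fit.tau2["obs"] == 0.0

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(8)
        y, g = balanced_oneway(rng, n_groups=15, k=7, tau2=2.0, sigma2=5.0)
        x = rng.normal(size=len(y))
        df = pd.DataFrame({"y": y + 0.8 * x, "x": x, "g": g})
        fit = lmm.fit_lmm("y ~ x", df, random=("g",))
        sm = smf.mixedlm("y ~ x", df, groups="g").fit(reml=True)
        np.testing.assert_allclose(fit.beta, sm.fe_params.to_numpy(),
                                   rtol=1e-4)
        assert fit.tau2["g"] == pytest.approx(
            float(sm.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.sigma2 == pytest.approx(float(sm.scale), rel=1e-3)


class TestWaldF:
    def test_balanced_oneway_equals_anova_f(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({"g": np.repeat(list("abcd"), 15),
                           "y": rng.normal(0, 1, 60)})
        fit = lmm.fit_lmm("y ~ g", df)
        F, dfn, dfd, p = lmm.wald_f(fit, "g")
        Fo, po = stats.f_oneway(*[df.y[df.g == k].to_numpy() for k in "abcd"])
        assert F == pytest.approx(Fo, rel=1e-10)
        assert dfn == 3
        assert dfd == pytest.approx(56, rel=1e-4)
        assert p == pytest.approx(po, rel=1e-4)

    def test_satterthwaite_df_approaches_residual_df_without_clustering(self):
        rng = np.random.default_rng(11)
        n, nb = 200, 40
        df = pd.DataFrame({"bird": np.repeat(np.arange(nb), n // nb),
                           "x": rng.normal(size=n)})
        df["y"] = 1 + 0.5 * df.x + rng.normal(0, 1, n)   # tau2 = 0 truth
        fit = lmm.fit_lmm("y ~ x", df, random=("bird",))
        _, _, dfd, _ = lmm.wald_f(fit, "x")
        assert dfd == pytest.approx(n - 2, rel=0.05)

    def test_between_cluster_term_has_reduced_df(self):
        rng = np.random.default_rng(12)
        nb, k = 24, 10
        grp = np.repeat(["a", "b", "c"], nb // 3)
        bird_fx = rng.normal(0, 2, nb)
        df = pd.DataFrame({"bird": np.repeat(np.arange(nb), k),
                           "g": np.repeat(grp, k)})
        df["y"] = np.repeat(bird_fx, k) + rng.normal(0, 1, nb * k)
        fit = lmm.fit_lmm("y ~ g", df, random=("bird",))
        _, _, dfd, _ = lmm.wald_f(fit, "g")
        # df should reflect the number of birds, not the number of rows
        assert dfd < nb + 5

    def test_unknown_term_raises(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"x": rng.normal(size=20),
                           "y": rng.normal(size=20)})
        fit = lmm.fit_lmm("y ~ x", df)
        with pytest.raises(lmm.LMMError, match="not in design"):
            lmm.wald_f(fit, "z")


class TestTukey:
    def test_two_levels_equals_unadjusted_t_test(self):
        rng = np.random.default_rng(20)
        df = pd.DataFrame({"g": np.repeat(["a", "b"], 15),
                           "y": rng.normal(0, 1, 30)})
        fit = lmm.fit_lmm("y ~ g", df)
        tk = lmm.tukey_pairwise(fit, "g")
        t, p = stats.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"])
        assert tk["p_adj"].iloc[0] == pytest.approx(p, rel=1e-6)

    def test_matches_statsmodels_tukeyhsd(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        rng = np.random.default_rng(21)
        df = pd.DataFrame({"g": np.repeat(list("abc"), 20),
                           "y": rng.normal(0, 1, 60)})
        df.loc[df.g == "c", "y"] += 1.0
        fit = lmm.fit_lmm("y ~ g", df)
        tk = lmm.tukey_pairwise(fit, "g")
        sm = pairwise_tukeyhsd(df.y, df.g)
        np.testing.assert_allclose(sorted(tk["p_adj"]),
                                   sorted(sm.pvalues), atol=1e-4)

    def test_identical_groups_have_high_adjusted_p(self):
        rng = np.random.default_rng(22)
        ps = []
        for r in range(10):
            df = pd.DataFrame({"g": np.repeat(list("abc"), 12),
                               "y": rng.normal(5, 1, 36)})
            fit = lmm.fit_lmm("y ~ g", df)
            ps.append(lmm.tukey_pairwise(fit, "g")["p_adj"].mean())
        assert np.mean(ps) > 0.5

    def test_adult_mass_pattern(self):
        # three groups patterned on the tracked males' body masses:
        # old-colony residents heaviest, new-colony residents lightest,
        # relocated intermediate and not separable from the residents of
        # the colony they joined
        import colonyforage as cf
        res_sig, reloc_ns = 0, 0
        for seed in range(12):
            adults = cf.simulate_adult_masses(cf.SimulationConfig(seed=seed))
            res = cf.analyse_adult_mass(adults)
            tk = res["tukey"].set_index("contrast")["p_adj"]
            by_pair = {frozenset(c.split(" - ")): p for c, p in tk.items()}
            res_sig += by_pair[frozenset({"zb_zb", "vl_vl"})] < 0.05
            reloc_ns += by_pair[frozenset({"vl_vl", "zb_vl"})] > 0.05
        assert res_sig >= 7
        assert reloc_ns >= 7
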