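"""Mixed models, ICC, likelihood-ratio arithmetic, moderated mediation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as ss

from vrss.errors import InvalidParameterError, ZeroVarianceError
from vrss.multilevel import (ModeratedMediation, fit_mixed, icc_1_1, lrt,
                             moderated_mediation, normalize,
                             simulate_mediation_data)


def direct_lmm_loglik(df, outcome, fixed, group, beta, var_b, var_w):
    """Independent oracle: sum of per-cluster multivariate-normal logpdfs."""
    ll = 0.0
    for _, sub in df.groupby(group):
        X = np.column_stack([np.ones(len(sub))]
                            + [sub[c].to_numpy() for c in fixed])
        mu = X @ beta
        cov = var_b * np.ones((len(sub), len(sub))) + var_w * np.eye(len(sub))
        ll += ss.multivariate_normal.logpdf(sub[outcome].to_numpy(), mu, cov)
    return ll


class TestNormalize:
    def test_two_point_sample(self):
        z = normalize([0.0, 10.0])
        assert z == pytest.approx([-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_idempotent_on_z_scores(self, rng):
        x = rng.normal(size=50)
        z = normalize(x)
        assert np.allclose(normalize(z), z, atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ZeroVarianceError):
            normalize(np.full(10, 4.0))


class TestICC:
    @pytest.mark.parametrize("vb,vw,expected", [
        (0.285, 0.742, 0.278),
        (0.112, 0.702, 0.138),
        (0.0, 5.0, 0.0),
    ])
    def test_values(self, vb, vw, expected):
        assert round(icc_1_1(vb, vw), 3) == pytest.approx(expected)

    @given(st.floats(min_value=1e-6, max_value=1e3),
           st.floats(min_value=1e-6, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, vb, vw, k):
        assert icc_1_1(k * vb, k * vw) == pytest.approx(icc_1_1(vb, vw),
                                                        rel=1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidParameterError):
            icc_1_1(0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(InvalidParameterError):
            icc_1_1(-0.1, 0.5)


class TestLRT:
    def test_printed_deviances(self):
        res = lrt(80.171, 75.493, df=1)
        assert res.lr_statistic == pytest.approx(4.678)
        assert round(res.critical_value_05, 2) == 3.84
        assert res.p < 0.05

    def test_equal_deviances(self):
        res = lrt(50.0, 50.0)
        assert res.lr_statistic == 0.0 and res.p == 1.0

    def test_negative_statistic_clamped(self):
        res = lrt(50.0, 51.0)
        assert res.lr_statistic == 0.0 and res.clamped

    def test_affine_reparameterization_invariance(self, rng):
        """Rescaling the outcome shifts both deviances, not their difference."""
        df = simulate_mediation_data(30, 4, a=0.5, b=-0.3, seed=2)
        f_null = fit_mixed(df, "y", [], "cluster")
        f_alt = fit_mixed(df, "y", ["x"], "cluster")
        df2 = df.assign(y=3.0 * df.y + 7.0)
        g_null = fit_mixed(df2, "y", [], "cluster")
        g_alt = fit_mixed(df2, "y", ["x"], "cluster")
        lr1 = lrt(f_null.deviance, f_alt.deviance).lr_statistic
        lr2 = lrt(g_null.deviance, g_alt.deviance).lr_statistic
        assert lr1 == pytest.approx(lr2, abs=5e-3)


class TestFitMixed:
    def test_no_cluster_effect_matches_ols(self, rng):
        """var_between=0 data: ICC ~ 0 and fixed effects equal OLS."""
        n = 240
        x = rng.normal(size=n)
        y = 1.5 + 2.0 * x + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x": x,
                           "g": np.repeat(np.arange(2), n // 2)})
        fit = fit_mixed(df, "y", ["x"], "g")
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.icc == pytest.approx(0.0, abs=0.02)
        assert fit.fixed_effects["const"][0] == pytest.approx(beta_ols[0],
                                                              abs=1e-4)
        assert fit.fixed_effects["x"][0] == pytest.approx(beta_ols[1],
                                                          abs=1e-4)

    def test_variance_recovery(self):
        """200 clusters x 5 with unit components recovered within 0.15."""
        vbs, vws = [], []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            cl = np.repeat(np.arange(200), 5)
            y = rng.normal(0, 1, 200)[cl] + rng.normal(0, 1, 1000) + 2.0
            fit = fit_mixed(pd.DataFrame({"y": y, "g": cl}), "y", [], "g")
            vbs.append(fit.var_between)
            vws.append(fit.var_within)
        assert np.mean(vbs) == pytest.approx(1.0, abs=0.15)
        assert np.mean(vws) == pytest.approx(1.0, abs=0.15)

    def test_deviance_matches_direct_loglik(self):
        """Internal consistency: deviance = -2 x loglik at returned params."""
        df = simulate_mediation_data(40, 5, a=0.6, b=-0.45, seed=4)
        fit = fit_mixed(df, "y", ["x", "m"], "cluster")
        beta = np.array([fit.fixed_effects[k][0] for k in ("const", "x", "m")])
        ll = direct_lmm_loglik(df, "y", ["x", "m"], "cluster", beta,
                               fit.var_between, fit.var_within)
        assert fit.deviance == pytest.approx(-2.0 * ll, abs=1e-4)

    def test_nested_model_deviance_monotone(self):
        df = simulate_mediation_data(30, 4, a=0.4, b=0.3, seed=6)
        null = fit_mixed(df, "y", [], "cluster")
        alt = fit_mixed(df, "y", ["x"], "cluster")
        assert alt.deviance <= null.deviance + 1e-6

    def test_singleton_clusters_hit_boundary_and_match_ols(self, rng):
        n = 60
        x = rng.normal(size=n)
        y = 0.5 + 1.2 * x + rng.normal(size=n)
        df = pd.DataFrame({"y": y, "x": x, "g": np.arange(n)})
        fit = fit_mixed(df, "y", ["x"], "g")
        X = np.column_stack([np.ones(n), x])
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.boundary
        assert fit.fixed_effects["x"][0] == pytest.approx(beta_ols[1], abs=1e-3)

    def test_random_slope_kind(self):
        df = simulate_mediation_data(50, 5, a=0.6, b=-0.4, seed=8)
        fit = fit_mixed(df, "y", ["x"], "cluster", random_slope="x")
        assert fit.model_kind == "random_slope"
        assert np.isfinite(fit.deviance)

    def test_single_cluster_rejected(self):
        df = pd.DataFrame({"y": np.arange(5.0), "g": np.zeros(5)})
        with pytest.raises(InvalidParameterError):
            fit_mixed(df, "y", [], "g")


class TestModeratedMediation:
    def test_path_recovery(self):
        """Configured a=0.6, b=-0.45 recovered within 0.1 at n=500."""
        df = simulate_mediation_data(100, 5, a=0.6, b=-0.45, c_prime=0.2,
                                     seed=10)
        res = ModeratedMediation(df, x="x", m="m", y="y", w="w",
                                 groups="cluster", standardize=False).fit()
        assert res.paths["a"].estimate == pytest.approx(0.6, abs=0.1)
        assert res.paths["b"].estimate == pytest.approx(-0.45, abs=0.1)
        assert res.mediated
        assert res.indirect_effect == pytest.approx(0.6 * -0.45, abs=0.12)

    def test_null_a_path_rarely_flagged(self):
        """With a=0 the X->M edge stays non-significant at ~nominal rate."""
        fp = 0
        n_seeds = 100
        for seed in range(n_seeds):
            df = simulate_mediation_data(30, 5, a=0.0, b=0.5, seed=seed)
            fit = fit_mixed(df, "m", ["x"], "cluster")
            fp += fit.fixed_effects["x"][2] < 0.05
        assert fp / n_seeds <= 0.12  # 5 % nominal + binomial tolerance

    def test_study_shaped_cohort_fits_all_legs(self, default_cohort_table):
        res = moderated_mediation(default_cohort_table, x="ssq_total",
                                  m="vlf_t6_10", y="physical_examination",
                                  w="frustration", grouping="ss_status")
        assert set(res.paths) >= {"c", "a", "b", "c_prime", "w"}
        for pe in res.paths.values():
            assert np.isfinite(pe.estimate) and np.isfinite(pe.se)
        assert res.lrt_mediator() is not None
        assert "ICC" in res.summary()

    def test_edges_report_sign_convention(self):
        df = simulate_mediation_data(60, 5, a=0.7, b=-0.5, seed=12)
        res = moderated_mediation(df, x="x", m="m", y="y", w=None,
                                  grouping="cluster")
        edges = {e["path"]: e for e in res.diagram_edges()}
        assert edges["a"]["sign"] == "positive"
        assert edges["b"]["sign"] == "inverse"

    def test_zero_variance_exposure_raises(self):
        df = pd.DataFrame({"x": np.zeros(20), "m": np.random.default_rng(0).normal(size=20),
                           "y": np.random.default_rng(1).normal(size=20),
                           "g": np.repeat([0, 1], 10)})
        with pytest.raises(ZeroVarianceError):
            ModeratedMediation(df, x="x", m="m", y="y", w=None, groups="g")

    def test_plot_diagram_draws_all_paths(self):
        import matplotlib
        matplotlib.use("Agg")
        df = simulate_mediation_data(30, 4, a=0.5, b=-0.4, seed=3)
        res = moderated_mediation(df, x="x", m="m", y="y", w="w",
                                  grouping="cluster")
        ax = res.plot_diagram()
        assert ax is not None and not ax.axison

    def test_bootstrap_indirect_brackets_point_estimate(self):
        df = simulate_mediation_data(50, 5, a=0.6, b=-0.45, seed=14)
        res = ModeratedMediation(df, x="x", m="m", y="y", w=None,
                                 groups="cluster", standardize=False).fit()
        boot = res.bootstrap_indirect(n_boot=200, seed=1)
        assert boot["ci_low"] <= boot["indirect"] <= boot["ci_high"]
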