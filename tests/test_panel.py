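import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from sppanel.panel import (
    PanelData,
    PanelError,
    RankError,
    decompose_effects,
    fit_panel_ols,
    fit_spatial_panel,
    hausman_test,
    lm_spatial_tests,
    lr_test,
    vif,
    wald_reduction_tests,
)
from sppanel.synthetic import SdmDgpConfig, lattice_weights, simulate_sdm_panel


def _cfg(**kw):
    base = dict(
        n_units=25,
        T=5,
        rho=0.4,
        beta=(1.0, -0.5),
        theta=(0.3, 0.0),
        covariate_spec=(("x1", 0, 1), ("x2", 0, 1)),
        sigma=0.2,
        seed=0,
    )
    base.update(kw)
    return SdmDgpConfig(**base)


@pytest.fixture(scope="module")
def w5():
    return lattice_weights(5, 5)


@pytest.fixture(scope="module")
def sdm_fit(w5):
    panel, _ = simulate_sdm_panel(w5, _cfg(fe_x_corr=0.5, seed=11))
    return fit_spatial_panel(panel, w5, "SDM", "both"), panel


class TestPanelData:
    def test_from_long_round_trip(self, w5):
        panel, _ = simulate_sdm_panel(w5, _cfg())
        again = PanelData.from_long(panel.to_long())
        assert np.allclose(again.y, panel.y)
        assert np.allclose(again.X, panel.X)
        assert again.unit_ids == panel.unit_ids

    def test_unbalanced_rejected(self, w5):
        panel, _ = simulate_sdm_panel(w5, _cfg())
        df = panel.to_long().iloc[:-1]
        with pytest.raises(PanelError, match="balanced"):
            PanelData.from_long(df)


class TestWithinOls:
    def test_noiseless_recovery(self, w5):
        cfg = _cfg(rho=0.0, theta=(0.0, 0.0), sigma=1e-10, fe_unit_sd=0.5)
        panel, truth = simulate_sdm_panel(w5, cfg)
        fit = fit_panel_ols(panel, effects="both")
        assert np.allclose(fit.beta.to_numpy(), truth.beta, atol=1e-8)

    def test_time_invariant_covariate_named_in_rank_error(self, w5):
        panel, _ = simulate_sdm_panel(w5, _cfg())
        panel.X[:, :, 1] = panel.X[:, 0:1, 1]  # freeze x2 over time
        with pytest.raises(RankError, match="x2"):
            fit_panel_ols(panel, effects="space")

    def test_fe_contamination_biases_pooled_not_within(self, w5):
        # unit effects correlated with x1 bias the pooled slope upward
        errs = {"pooled": [], "both": []}
        for s in range(20):
            cfg = _cfg(fe_x_corr=0.8, fe_unit_sd=1.0, rho=0.0, theta=(0.0, 0.0), seed=s)
            panel, truth = simulate_sdm_panel(w5, cfg)
            for eff in errs:
                fit = fit_panel_ols(panel, effects=eff)
                errs[eff].append(fit.beta["x1"] - truth.beta[0])
        assert abs(np.mean(errs["both"])) < abs(np.mean(errs["pooled"]))
        assert abs(np.mean(errs["pooled"])) > 0.1


class TestLmBattery:
    def test_statistics_nonnegative(self, w5):
        for s in range(5):
            panel, _ = simulate_sdm_panel(w5, _cfg(seed=s))
            lm = lm_spatial_tests(fit_panel_ols(panel, "both"), w5)
            assert all(t.statistic >= 0 for t in lm.values())
            assert all(0 < t.p <= 1 for t in lm.values())

    def test_detects_strong_lag_dependence(self, w5):
        cfg = _cfg(rho=0.6, theta=(0.0, 0.0), seed=2)
        panel, _ = simulate_sdm_panel(w5, cfg)
        lm = lm_spatial_tests(fit_panel_ols(panel, "both"), w5)
        assert lm["LM-lag"].p < 0.01


class TestSpatialML:
    def test_rho_zero_constraint_collapses_to_within_ols(self, w5):
        panel, _ = simulate_sdm_panel(w5, _cfg(seed=5))
        ols = fit_panel_ols(panel, "both")
        sar0 = fit_spatial_panel(panel, w5, "SAR", "both", constrain_rho=0.0)
        assert np.allclose(
            sar0.beta.to_numpy(), ols.beta.to_numpy(), atol=1e-12
        )

    def test_nested_loglik_ordering(self, w5):
        panel, _ = simulate_sdm_panel(w5, _cfg(seed=6))
        ll_ols = fit_panel_ols(panel, "both").loglik
        ll_sar = fit_spatial_panel(panel, w5, "SAR", "both").loglik
        ll_sdm = fit_spatial_panel(panel, w5, "SDM", "both").loglik
        assert ll_sdm >= ll_sar - 1e-8 >= ll_ols - 2e-8

    @pytest.mark.parametrize("seed", range(8))
    def test_optimum_matches_dense_grid_search(self, seed):
        # concentrated likelihood at rho_hat beats a 1e-3 grid within a step
        rng = np.random.default_rng(seed)
        rows = int(rng.integers(3, 6))
        w = lattice_weights(rows, 5)
        cfg = _cfg(n_units=rows * 5, T=4, rho=float(rng.uniform(-0.5, 0.7)), seed=seed)
        panel, _ = simulate_sdm_panel(w, cfg)
        fit = fit_spatial_panel(panel, w, "SDM", "both")

        neg_conc = fit._cache["neg_conc"]
        grid = np.arange(-0.95, 0.999, 1e-3)
        vals = [-neg_conc(r) for r in grid]
        best = grid[int(np.argmax(vals))]
        assert abs(fit.rho - best) <= 1e-3 + 1e-9

    def test_cross_sectional_sar_matches_full_likelihood_brute_force(self):
        # T=1 pooled SAR against an independent, non-concentrated ML oracle
        w = lattice_weights(4, 4)
        rng = np.random.default_rng(8)
        n = 16
        X = rng.standard_normal((n, 1, 2))
        Wm = w.W
        A_inv = np.linalg.inv(np.eye(n) - 0.4 * Wm)
        y = A_inv @ (0.5 + X[:, 0, :] @ np.array([1.0, -0.5]) + 0.3 * rng.standard_normal(n))
        panel = PanelData(w.regions.ids, (2020,), y[:, None], X, ("x1", "x2"))
        fit = fit_spatial_panel(panel, w, "SAR", "pooled")

        Z = np.column_stack([np.ones(n), X[:, 0, :]])

        def neg_full(params):
            rho, s2 = params[0], np.exp(params[1])
            b = params[2:]
            if not -0.99 < rho < 0.99:
                return 1e10
            e = y - rho * (Wm @ y) - Z @ b
            _, logdet = np.linalg.slogdet(np.eye(n) - rho * Wm)
            return (
                0.5 * n * np.log(2 * np.pi * s2) - logdet + float(e @ e) / (2 * s2)
            )

        x0 = np.concatenate([[0.0, 0.0], np.zeros(3)])
        res = optimize.minimize(neg_full, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert res.success
        assert fit.rho == pytest.approx(res.x[0], abs=1e-6)
        assert np.allclose(fit.beta.to_numpy(), res.x[2:], atol=1e-5)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_analytic_vcov_close_to_numerical_hessian(self, sdm_fit, w5):
        fit, panel = sdm_fit
        names = list(fit._cache["names"])

        def neg_full(p):
            rho = p[len(names)]
            s2 = np.exp(p[len(names) + 1])
            delta = p[: len(names)]
            f = fit_spatial_panel(panel, w5, "SDM", "both", constrain_rho=rho)
            Z = f._cache["Z"]
            from sppanel.panel import _demean, _stack, _apply_W

            yv = _stack(_demean(panel.y, "both"))
            Wyv = _stack(_demean(_apply_W(panel.y, w5.W), "both"))
            e = yv - rho * Wyv - Z @ delta
            omega = np.linalg.eigvalsh(
                w5.W0 / np.sqrt(np.outer(w5.W0.sum(1), w5.W0.sum(1)))
            )
            nobs = panel.n * panel.T
            return (
                0.5 * nobs * np.log(2 * np.pi * s2)
                - panel.T * np.sum(np.log(1 - rho * omega))
                + float(e @ e) / (2 * s2)
            )

        from sppanel.panel import _num_hessian, _sar_sdm_vcov

        p0 = np.concatenate(
            [fit.beta.to_numpy(), fit.theta.to_numpy(), [fit.rho, np.log(fit.sigma2_ml)]]
        )
        H = _num_hessian(neg_full, p0, rel_step=1e-5)
        vc_num = np.linalg.inv(H)[: len(names) + 1, : len(names) + 1]
        delta = np.concatenate([fit.beta.to_numpy(), fit.theta.to_numpy()])
        vc_ana = _sar_sdm_vcov(
            fit._cache["Z"], delta, fit.rho, fit.sigma2_ml, w5.W,
            panel.n, panel.T, names,
        ).iloc[: len(names) + 1, : len(names) + 1].to_numpy()
        se_ana = np.sqrt(np.diag(vc_ana))
        se_num = np.sqrt(np.diag(vc_num))
        # slope SEs agree tightly; the rho cell mixes trace terms where
        # expected and observed information differ more at this sample size
        assert np.allclose(se_ana[:-1], se_num[:-1], rtol=0.05)
        assert se_ana[-1] == pytest.approx(se_num[-1], rel=0.2)


class TestSpecificationTests:
    def test_wald_nonnegative_and_valid_p(self, sdm_fit):
        fit, _ = sdm_fit
        wald = wald_reduction_tests(fit)
        for t in wald.values():
            assert t.statistic >= 0
            assert 0 < t.p <= 1

    def test_lr_identical_fits_zero(self, sdm_fit):
        fit, _ = sdm_fit
        res = lr_test(fit, fit, df=2)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_lr_rejects_reversed_nesting(self, w5, sdm_fit):
        fit, panel = sdm_fit
        sar = fit_spatial_panel(panel, w5, "SAR", "both")
        with pytest.raises(PanelError, match="nested"):
            lr_test(fit, sar, df=2)

    def test_lr_wald_asymptotically_close(self, w5):
        # SDM-vs-SAR LR and Wald statistics correlate strongly across draws
        lrs, walds = [], []
        for s in range(40):
            panel, _ = simulate_sdm_panel(w5, _cfg(theta=(0.15, 0.1), T=8, seed=100 + s))
            sdm = fit_spatial_panel(panel, w5, "SDM", "both")
            sar = fit_spatial_panel(panel, w5, "SAR", "both")
            lrs.append(lr_test(sar, sdm, df=2).statistic)
            walds.append(wald_reduction_tests(sdm)["Wald SDM->SAR"].statistic)
        assert np.corrcoef(lrs, walds)[0, 1] > 0.9

    def test_hausman_zero_difference(self, sdm_fit):
        fit, _ = sdm_fit
        res = hausman_test(fit, fit)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hausman_mismatched_covariates_rejected(self, w5, sdm_fit):
        fit, panel = sdm_fit
        sar = fit_spatial_panel(panel, w5, "SAR", "both")
        other = fit_panel_ols(panel, "both")
        other.beta.index = ["a", "b"]
        with pytest.raises(PanelError, match="common"):
            hausman_test(other, fit)


class TestEffects:
    def test_rho_zero_closed_form(self, w5):
        panel, _ = simulate_sdm_panel(w5, _cfg(seed=13))
        fit = fit_spatial_panel(panel, w5, "SDM", "both", constrain_rho=0.0)
        eff = decompose_effects(fit, w5, n_draws=50, seed=1)
        assert np.allclose(eff.direct, fit.beta.to_numpy(), atol=1e-12)
        assert np.allclose(eff.indirect, fit.theta.to_numpy(), atol=1e-12)

    def test_sar_total_geometric_series(self, w5):
        panel, _ = simulate_sdm_panel(w5, _cfg(theta=(0.0, 0.0), seed=14))
        fit = fit_spatial_panel(panel, w5, "SAR", "both", constrain_rho=0.5)
        eff = decompose_effects(fit, w5, n_draws=50, seed=2)
        assert np.allclose(eff.total, 2.0 * fit.beta.to_numpy(), atol=1e-10)

    def test_total_is_direct_plus_indirect(self, sdm_fit, w5):
        fit, _ = sdm_fit
        eff = decompose_effects(fit, w5, n_draws=100, seed=3)
        assert np.allclose(eff.total, eff.direct + eff.indirect, atol=1e-12)

    def test_seed_determinism(self, sdm_fit, w5):
        fit, _ = sdm_fit
        a = decompose_effects(fit, w5, n_draws=100, seed=9)
        b = decompose_effects(fit, w5, n_draws=100, seed=9)
        assert np.array_equal(a.direct_se, b.direct_se)


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        # zero-mean mutually orthogonal cosine contrasts
        t = np.arange(24)
        X = np.column_stack([np.cos(2 * np.pi * j * t / 24) for j in (1, 2, 3)])
        tab = vif(X)
        assert np.allclose(tab["vif"], 1.0, atol=1e-10)

    def test_aux_r2_09_gives_ten(self):
        # construct x3 with exact auxiliary R^2 = 0.9 against x1
        rng = np.random.default_rng(1)
        x1 = rng.standard_normal(1000)
        u = rng.standard_normal(1000)
        D = np.column_stack([np.ones(1000), x1])
        u = u - D @ np.linalg.lstsq(D, u, rcond=None)[0]  # u ⟂ {1, x1}
        x1c = x1 - x1.mean()
        x3 = np.sqrt(0.9) * x1c / np.linalg.norm(x1c) + np.sqrt(0.1) * u / np.linalg.norm(u)
        tab = vif(np.column_stack([x1, x3]), ["x1", "x3"])
        assert tab["vif"].iloc[1] == pytest.approx(10.0, abs=1e-8)

    def test_exact_collinearity_flagged(self):
        rng = np.random.default_rng(2)
        x1 = rng.standard_normal(100)
        x2 = rng.standard_normal(100)
        tab = vif(np.column_stack([x1, x2, x1 + x2]), ["x1", "x2", "x3"])
        assert tab["collinear"].all()
        assert np.isinf(tab["vif"]).all()
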