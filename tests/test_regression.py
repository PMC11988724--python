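"""Poisson/NB2 fitting, overdispersion diagnostics, effect transforms, Vuong."""

import numpy as np
import pandas as pd
import pytest

from promotif import (ModelSpec, SimulationConfig, effects_table, fit_model,
                      fit_group_interaction, fit_negbin, fit_poisson,
                      gen_count_dataset, overdispersion_test, percent_change,
                      predict_expected, rate_ratio, vuong_test)

INTERCEPT_ONLY = ModelSpec(response="y", predictors=[], family="poisson")


def _df(y, **cols):
    return pd.DataFrame({"y": y, **cols})


class TestPoisson:
    def test_intercept_only_log_mean(self):
        fit = fit_poisson(_df([1, 2, 3]), INTERCEPT_ONLY)
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_two_group_closed_form(self):
        # group means 2 and 6: slope = log(6/2) = log 3
        y = [2, 2, 2, 2, 6, 6, 6, 6]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        fit = fit_poisson(_df(y, g=g),
                          ModelSpec(response="y", predictors=["g"],
                                    family="poisson"))
        assert fit.beta[1] == pytest.approx(np.log(3.0), abs=1e-7)
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-7)

    def test_all_zero_response_raises(self):
        with pytest.raises(RuntimeError):
            fit_poisson(_df([0, 0, 0, 0]), INTERCEPT_ONLY)

    def test_rank_deficient_design_named(self):
        df = _df([1, 2, 3, 4], a=[1.0, 2.0, 3.0, 4.0], b=[2.0, 4.0, 6.0, 8.0])
        with pytest.raises(ValueError, match="collinear"):
            fit_poisson(df, ModelSpec(response="y", predictors=["a", "b"],
                                      family="poisson"))

    def test_non_integer_response_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            fit_poisson(_df([1.5, 2.0, 3.0]), INTERCEPT_ONLY)

    def test_information_criteria_identities(self):
        cfg = SimulationConfig(seed=3, n_genes=300, theta=np.inf)
        df, _ = gen_count_dataset(cfg)
        fit = fit_poisson(df, ModelSpec(family="poisson"))
        k = len(fit.beta)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
        assert fit.bic == pytest.approx(-2 * fit.loglik + np.log(fit.n_obs) * k)
        assert fit.residual_deviance <= fit.null_deviance


class TestOverdispersion:
    def test_calibrated_under_poisson(self):
        cfg = SimulationConfig(seed=0, n_genes=500, theta=np.inf)
        df, _ = gen_count_dataset(cfg)
        od = overdispersion_test(fit_poisson(df, ModelSpec(family="poisson")))
        assert 0.8 <= od.ratio <= 1.2
        assert od.p_value > 0.05 and not od.overdispersed

    def test_detects_nb_overdispersion(self):
        cfg = SimulationConfig(seed=1, n_genes=500, theta=1.0)
        df, _ = gen_count_dataset(cfg)
        od = overdispersion_test(fit_poisson(df, ModelSpec(family="poisson")))
        assert od.ratio > 1.4
        assert od.p_value < 0.01 and od.overdispersed


class TestNegBin:
    def test_poisson_limit(self):
        cfg = SimulationConfig(seed=2, n_genes=800, theta=np.inf)
        df, _ = gen_count_dataset(cfg)
        with pytest.warns(UserWarning, match="Poisson-equivalent"):
            nb = fit_negbin(df)
        pois = fit_poisson(df, ModelSpec(family="poisson"))
        assert nb.theta > 50
        assert np.linalg.norm(nb.beta - pois.beta) < 1e-3

    def test_parameter_recovery(self):
        cfg = SimulationConfig(seed=0, n_genes=2000, theta=1.3,
                               beta=np.array([-0.8, 0.11, 4.3]))
        df, truth = gen_count_dataset(cfg)
        fit = fit_negbin(df)
        ci = fit.conf_int()
        for i, b in enumerate(truth.true_beta):
            assert ci[i, 0] <= b <= ci[i, 1]
        assert 0.9 <= fit.theta <= 1.8

    def test_intercept_only_near_log_mean(self):
        cfg = SimulationConfig(seed=4, n_genes=1000, theta=1.3,
                               beta=np.array([np.log(3.0), 0.0, 0.0]))
        df, _ = gen_count_dataset(cfg)
        spec = ModelSpec(response="distal_count", predictors=[],
                         family="negbin")
        fit = fit_negbin(df, spec)
        assert fit.beta[0] == pytest.approx(np.log(df["distal_count"].mean()),
                                            abs=1e-4)


class TestEffects:
    def test_published_worked_examples(self):
        assert percent_change(0.10986) == 11.6
        assert rate_ratio(0.2995) == 1.34

    def test_null_effect(self):
        assert percent_change(0.0) == 0.0
        assert rate_ratio(0.0) == 1.0

    def test_table_consistency(self):
        cfg = SimulationConfig(seed=5, n_genes=400, theta=np.inf)
        df, _ = gen_count_dataset(cfg)
        fit = fit_poisson(df, ModelSpec(family="poisson"))
        eff = effects_table(fit)
        assert np.allclose(eff["rate_ratio"], np.exp(fit.beta))
        assert (eff["rr_low"] <= eff["rr_high"]).all()
        assert (eff["rate_ratio"] > 0).all()


class TestVuong:
    def test_self_comparison_indistinguishable(self):
        cfg = SimulationConfig(seed=6, n_genes=300, theta=np.inf)
        df, _ = gen_count_dataset(cfg)
        fit = fit_poisson(df, ModelSpec(family="poisson"))
        v = vuong_test(fit, fit)
        assert v.statistic == 0.0 and v.preferred == "indistinguishable"

    def test_prefers_nb_on_overdispersed_data(self):
        cfg = SimulationConfig(seed=7, n_genes=1000, theta=1.0)
        df, _ = gen_count_dataset(cfg)
        nb = fit_negbin(df)
        pois = fit_poisson(df, ModelSpec(family="poisson"))
        v = vuong_test(nb, pois)
        assert v.statistic > 0 and v.p_value < 0.05
        assert v.preferred == "model_a"
        swapped = vuong_test(pois, nb)
        assert swapped.statistic == pytest.approx(-v.statistic)

    def test_response_mismatch_rejected(self):
        cfg = SimulationConfig(seed=8, n_genes=100, theta=np.inf)
        df, _ = gen_count_dataset(cfg)
        df2 = df.copy()
        df2["distal_count"] = df2["distal_count"] + 1
        a = fit_poisson(df, ModelSpec(family="poisson"))
        b = fit_poisson(df2, ModelSpec(family="poisson"))
        with pytest.raises(ValueError):
            vuong_test(a, b)


class TestGroupInteraction:
    def test_recovers_interaction_effect(self):
        cfg = SimulationConfig(seed=9, n_genes=2000, theta=np.inf,
                               beta=np.array([-0.8, 0.11, 4.3, 0.1, 0.3]))
        df, truth = gen_count_dataset(cfg, with_group=True)
        fit = fit_group_interaction(
            df, ModelSpec(family="poisson"), group="group")
        i = fit.names.index("plus_count:group[oGPCR]")
        # design codes the second level; truth coded GPCR-MetS==1, so the
        # oGPCR interaction coefficient estimates -0.3
        ci = fit.conf_int()
        assert ci[i, 0] <= -0.3 <= ci[i, 1]

    def test_type_one_error_when_no_group_effect(self):
        """Wald test of the interaction keeps ~5% size under the null."""
        rejections = 0
        reps = 100
        for r in range(reps):
            cfg = SimulationConfig(seed=1000 + r, n_genes=400, theta=np.inf,
                                   beta=np.array([-0.5, 0.12, 2.0, 0.0, 0.0]))
            df, _ = gen_count_dataset(cfg, with_group=True)
            fit = fit_group_interaction(df, ModelSpec(family="poisson"),
                                        group="group")
            i = fit.names.index("plus_count:group[oGPCR]")
            if fit.wald_pvalues()[i] < 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 1e-9

    def test_single_level_group_rejected(self):
        cfg = SimulationConfig(seed=10, n_genes=100, theta=np.inf)
        df, _ = gen_count_dataset(cfg)
        df["group"] = "oGPCR"
        with pytest.raises(ValueError):
            fit_group_interaction(df, ModelSpec(family="poisson"))


class TestPredict:
    @pytest.fixture()
    def fit(self):
        cfg = SimulationConfig(seed=11, n_genes=600, theta=np.inf)
        df, _ = gen_count_dataset(cfg)
        return fit_poisson(df, ModelSpec(family="poisson"))

    def test_baseline_is_exp_intercept(self, fit):
        grid = pd.DataFrame({"plus_count": [0.0], "similarity": [0.0]})
        out = predict_expected(fit, grid)
        assert out["expected"][0] == pytest.approx(np.exp(fit.beta[0]))

    def test_monotone_in_positive_coefficient(self, fit):
        assert fit.beta[1] > 0
        grid = pd.DataFrame({"plus_count": np.arange(0.0, 10.0),
                             "similarity": 0.6})
        out = predict_expected(fit, grid)
        assert (np.diff(out["expected"]) > 0).all()

    def test_delta_method_matches_parametric_bootstrap(self, fit):
        rng = np.random.default_rng(12)
        grid = pd.DataFrame({"plus_count": [5.0], "similarity": [0.7]})
        out = predict_expected(fit, grid)
        mus = []
        data = pd.DataFrame({"plus_count": fit.X[:, 1],
                             "similarity": fit.X[:, 2]})
        for _ in range(200):
            yb = rng.poisson(fit.fitted)
            bfit = fit_poisson(data.assign(distal_count=yb),
                               ModelSpec(family="poisson"))
            mus.append(predict_expected(bfit, grid)["expected"][0])
        lo, hi = np.quantile(mus, [0.025, 0.975])
        width_delta = out["ci_high"][0] - out["ci_low"][0]
        width_boot = hi - lo
        assert width_delta == pytest.approx(width_boot, rel=0.25)

    def test_grid_mismatch(self, fit):
        with pytest.raises((ValueError, KeyError)):
            predict_expected(fit, pd.DataFrame({"wrong": [1.0]}))
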