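import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from pvsmorph.cohort_stats import (chi_sq, compare_models, fit_beta_regression,
                                   fit_linear, fit_logistic, pearson_corr,
                                   percentage, polyserial_corr,
                                   run_association_battery, squeeze_transform,
                                   welch_t, zscore)
from pvsmorph.phantom import CohortSimSpec, simulate_cohort


class TestSqueezeTransform:
    def test_half_is_fixed_point(self):
        for n in (2, 10, 533):
            assert squeeze_transform(np.array([0.5]), n)[0] == pytest.approx(0.5)

    def test_zero_at_cohort_n(self):
        out = squeeze_transform(np.array([0.0]), 533)
        assert out[0] == pytest.approx(0.5 / 533)
        assert out[0] == pytest.approx(9.3809e-4, rel=1e-4)

    def test_zero_at_n_two(self):
        assert squeeze_transform(np.array([0.0]), 2)[0] == pytest.approx(0.25)

    def test_maps_into_open_interval_and_preserves_order(self):
        y = np.array([0.0, 1e-6, 0.2, 0.5, 0.93])
        out = squeeze_transform(y, 50)
        assert np.all(out > 0) and np.all(out < 1)
        assert np.all(np.diff(out) > 0)

    def test_affine(self):
        y = np.array([0.1, 0.3, 0.7])
        out = squeeze_transform(y, 100)
        slope = (out[2] - out[0]) / (y[2] - y[0])
        np.testing.assert_allclose(out, out[0] + slope * (y - y[0]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            squeeze_transform(np.array([-0.1]), 10)
        with pytest.raises(ValueError):
            squeeze_transform(np.array([1.1]), 10)
        with pytest.raises(ValueError):
            squeeze_transform(np.array([0.5]), 1)


class TestFitLinear:
    def test_perfect_fit(self):
        x = np.arange(20.0)
        res = fit_linear(x, pd.DataFrame({"x": x}), "x")
        assert res.effect == pytest.approx(1.0, abs=1e-10)
        assert res.ci_high - res.ci_low < 1e-8

    def test_permuted_outcome_ci_covers_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = rng.permutation(x)
        res = fit_linear(y, pd.DataFrame({"x": x}), "x")
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_rank_deficiency_rejected(self):
        x = np.ones(30)
        with pytest.raises(ValueError, match="rank"):
            fit_linear(np.arange(30.0), pd.DataFrame({"x": x}), "x")

    def test_recovery_at_cohort_n(self):
        # true standardized effect 0.44, n=533, moderate noise: the CI should
        # cover the truth in >= 90/100 replicates
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=533)
            y = 0.44 * x + rng.normal(scale=0.9, size=533)
            res = fit_linear(y, pd.DataFrame({"x": x}), "x")
            hits += res.ci_low <= 0.44 <= res.ci_high
        assert hits >= 90

    def test_aic_bic_identities(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        y = x + rng.normal(size=100)
        res = fit_linear(y, pd.DataFrame({"x": x}), "x")
        assert res.aic == pytest.approx(2 * res.n_params - 2 * res.loglik)
        assert res.bic == pytest.approx(res.n_params * np.log(res.n) - 2 * res.loglik)


class TestFitLogistic:
    def test_two_by_two_or_equals_cross_product_ratio(self):
        # exposed: 10 events / 20 non-events; unexposed: 30 / 40
        a, b, c, d = 10, 20, 30, 40
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        res = fit_logistic(y, pd.DataFrame({"x": x}), "x")
        assert res.effect == pytest.approx((a * d) / (b * c), abs=1e-6)
        assert res.effect == pytest.approx(0.666667, abs=1e-6)

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_logistic(np.zeros(50), pd.DataFrame({"x": np.arange(50.0)}), "x")

    def test_perfect_separation_rejected(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        with pytest.raises((ValueError, RuntimeError)):
            fit_logistic(y, pd.DataFrame({"x": x}), "x")

    def test_null_effect_ci_covers_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        y = (rng.uniform(size=5000) < 0.3).astype(float)
        res = fit_logistic(y, pd.DataFrame({"x": x}), "x")
        assert res.ci_low <= 1.0 <= res.ci_high


class TestFitBetaRegression:
    def test_intercept_only_symmetric_outcome(self):
        rng = np.random.default_rng(3)
        y = np.clip(rng.normal(0.5, 0.1, size=500), 0.01, 0.99)
        res = fit_beta_regression(y, pd.DataFrame(index=range(500)), "const")
        se = res.bse["const"]
        assert abs(res.params["const"]) < 2 * se

    def test_boundary_values_rejected(self):
        y = np.array([0.0, 0.5, 0.7])
        with pytest.raises(ValueError, match="squeeze"):
            fit_beta_regression(y, pd.DataFrame({"x": [1.0, 2.0, 3.0]}), "x")

    def test_parameter_recovery_20_seed_average(self):
        b_est, phi_est = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=2000)
            mu = expit(-2.0 + 0.4 * x)
            y = rng.beta(mu * 10.0, (1 - mu) * 10.0)
            res = fit_beta_regression(y, pd.DataFrame({"x": x}), "x")
            b_est.append(res.effect)
            phi_est.append(res.phi)
        assert np.mean(b_est) == pytest.approx(0.4, abs=0.1)
        assert np.mean(phi_est) == pytest.approx(10.0, rel=0.2)

    def test_loglik_is_local_optimum(self):
        from scipy.stats import beta as beta_dist

        rng = np.random.default_rng(4)
        x = rng.normal(size=400)
        mu = expit(-1.0 + 0.5 * x)
        y = rng.beta(mu * 8.0, (1 - mu) * 8.0)
        res = fit_beta_regression(y, pd.DataFrame({"x": x}), "x")

        def loglik(b0, b1, phi):
            m = expit(b0 + b1 * x)
            return beta_dist.logpdf(y, m * phi, (1 - m) * phi).sum()

        b0, b1, phi = res.params["const"], res.params["x"], res.phi
        best = loglik(b0, b1, phi)
        assert best == pytest.approx(res.loglik, rel=1e-6)
        for db0 in (-0.05, 0.0, 0.05):
            for db1 in (-0.05, 0.0, 0.05):
                assert loglik(b0 + db0, b1 + db1, phi) <= best + 1e-9


class TestPolyserial:
    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=5000)
        o = rng.integers(0, 5, size=5000)
        assert abs(polyserial_corr(o, x)["r"]) < 0.03

    def test_latent_rho_recovery(self):
        rng = np.random.default_rng(6)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        o = np.digitize(z[:, 0], [-1.2, -0.4, 0.5, 1.3])
        r = polyserial_corr(o, z[:, 1])
        assert r["r"] == pytest.approx(0.6, abs=0.05)
        assert r["ci_low"] < 0.6 < r["ci_high"]

    def test_exceeds_attenuated_pearson(self):
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=5000)
        o = np.digitize(z[:, 0], [-1.2, -0.4, 0.5, 1.3])
        poly = polyserial_corr(o, z[:, 1])["r"]
        naive = pearson_corr(o.astype(float), z[:, 1])["r"]
        assert poly > naive

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            polyserial_corr(np.ones(100), np.random.default_rng(0).normal(size=100))


class TestSimpleTests:
    def test_pearson_anticorrelated(self):
        x = np.arange(50.0)
        r = pearson_corr(x, -x)
        assert r["r"] == pytest.approx(-1.0)

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(10), np.arange(10.0))

    def test_welch_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(x, x.copy())
        assert res["t"] == pytest.approx(0.0)
        assert res["ci_low"] < 0 < res["ci_high"]

    def test_welch_satterthwaite_df(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 4.0, 6.0])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        expected_df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
        assert welch_t(a, b)["df"] == pytest.approx(expected_df)

    def test_chi_squared_hand_computed(self):
        res = chi_sq([[10, 20], [30, 40]])
        assert res["chi2"] == pytest.approx(0.7937, abs=1e-4)
        assert res["dof"] == 1
        lo, hi = res["prop_diff_ci"]
        assert lo < res["prop_diff"] < hi


class TestPercentage:
    def test_basic(self):
        assert percentage(540, 700, 0) == 77.0
        assert percentage(254, 533) == 47.65

    def test_invalid_total(self):
        with pytest.raises(ValueError):
            percentage(1, 0)


class TestCompareModels:
    def _model(self, seed, extra_noise_col=False, n=2000):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        X = pd.DataFrame({"x": x})
        if extra_noise_col:
            X["junk"] = rng.normal(size=n)
        return fit_linear(y, X, "x", label="junk" if extra_noise_col else "base")

    def test_identical_models_no_flag(self):
        m = self._model(0)
        rep = compare_models([m], m)
        assert rep["models"][0]["delta_aic"] == 0.0
        assert rep["models"][0]["delta_bic"] == 0.0
        assert not rep["models"][0]["practical_improvement"]

    def test_pure_noise_parameter_pays_log_n_in_bic(self):
        n = 2000
        base = self._model(1, extra_noise_col=False, n=n)
        bigger = self._model(1, extra_noise_col=True, n=n)
        d_bic = bigger.bic - base.bic
        # penalty ln(n) minus a chi2_1 improvement in fit
        assert np.log(n) - 5 < d_bic <= np.log(n) + 0.1

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError, match="n"):
            compare_models([self._model(2, n=100)], self._model(2, n=200))

    def test_size_model_flagged_over_noisy_count_proxy(self):
        from pvsmorph.cohort_stats import zscore
        flagged = 0
        for seed in range(50):
            spec = CohortSimSpec(n_subjects=533, seed=seed,
                                 beta_reg_coefs=(-4.6, 0.5),
                                 metric_loadings={"pvs_mean_size": 0.98,
                                                  "pvs_count": 0.45})
            coh = simulate_cohort(spec)
            y = squeeze_transform(coh["wmh_pct_icv"].to_numpy(), len(coh))
            fits = {}
            for m in ("pvs_mean_size", "pvs_count"):
                X = coh[["age", "sex", "hypertension"]].copy()
                X[m] = zscore(coh[m])
                fits[m] = fit_beta_regression(y, X, m, label=m)
            rep = compare_models([fits["pvs_mean_size"]], fits["pvs_count"])
            flagged += rep["models"][0]["practical_improvement"]
        assert flagged >= 40  # >= 80% of 50 seeds


class TestAssociationBattery:
    def test_full_grid_of_models(self):
        coh = simulate_cohort(CohortSimSpec(n_subjects=400, seed=9))
        res = run_association_battery(coh)
        assert set(res["family"]) == {"linear", "logistic", "beta"}
        assert len(res) == 8 * 6  # 8 outcomes x (5 measures + visual reference)
        assert (res["ci_low"] <= res["ci_high"]).all()

    def test_covariate_exclusion_rule(self):
        # hypertension never appears as its own covariate: the model for the
        # hypertension outcome must fit without error and differ from others
        coh = simulate_cohort(CohortSimSpec(n_subjects=400, seed=10))
        res = run_association_battery(coh, pvs_measures=("pvs_mean_size",),
                                      include_visual_reference=False)
        assert "hypertension" in set(res["outcome"])
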