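import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from streamdna.covariate_glm import (
    Covariate,
    DesignSpec,
    GlmFit,
    RankDeficientError,
    aicc,
    all_subsets,
    build_design,
    camera_rates,
    detection_curves,
    fit_glm,
    fit_glm_matrix,
    predict_with_se,
)
from streamdna.io_schemas import CameraDeployment


class TestFitGlm:
    def test_intercept_only_poisson_is_log_mean(self):
        X = np.ones((3, 1))
        fit = fit_glm_matrix(X, np.array([3.0, 5.0, 7.0]), "poisson")
        assert fit.beta[0] == pytest.approx(np.log(5.0), abs=1e-8)

    def test_intercept_only_logistic_is_logit_of_mean(self):
        X = np.ones((4, 1))
        fit = fit_glm_matrix(X, np.array([1.0, 0.0, 1.0, 1.0]), "binomial")
        assert fit.beta[0] == pytest.approx(np.log(3.0), abs=1e-8)

    def test_two_covariate_poisson_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        X = np.column_stack([np.ones(20), rng.normal(size=20),
                             rng.normal(size=20)])
        y = rng.poisson(np.exp(0.3 + 0.6 * X[:, 1] - 0.4 * X[:, 2]))
        fit = fit_glm_matrix(X, y, "poisson")
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)
        np.testing.assert_allclose(fit.covariance, ref.cov_params(), atol=1e-6)

    def test_logistic_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = (rng.uniform(size=80) < expit(-0.2 + 0.9 * X[:, 1])).astype(float)
        fit = fit_glm_matrix(X, y, "binomial")
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-8)

    def test_rank_deficient_names_columns(self):
        X = np.column_stack([np.ones(30), np.arange(30.0), 2 * np.arange(30.0)])
        with pytest.raises(RankDeficientError, match="x"):
            fit_glm_matrix(X, np.ones(30), "poisson")

    def test_separation_flags_nonconvergence(self):
        X = np.column_stack([np.ones(30), np.r_[np.zeros(15), np.ones(15)]])
        y = np.r_[np.zeros(15), np.ones(15)]
        fit = fit_glm_matrix(X, y, "binomial")
        assert not fit.converged

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n > k"):
            fit_glm_matrix(np.ones((2, 1)), np.array([1.0, 2.0]), "poisson")


class TestDesignBuilder:
    def test_factor_treatment_coding_with_reference(self):
        df = pd.DataFrame({"diet": ["omnivore", "carnivore", "herbivore"]})
        X, names, levels = build_design(
            df, [Covariate("diet", kind="factor", reference="carnivore")])
        assert names == ["Intercept", "diet[herbivore]", "diet[omnivore]"]
        assert levels["diet"][0] == "carnivore"
        np.testing.assert_array_equal(X[1], [1.0, 0.0, 0.0])  # reference row

    def test_log_transform(self):
        df = pd.DataFrame({"body_mass": [1.0, np.e]})
        X, names, _ = build_design(
            df, [Covariate("body_mass", transform="log")])
        assert names == ["Intercept", "log(body_mass)"]
        np.testing.assert_allclose(X[:, 1], [0.0, 1.0])

    def test_unseen_level_in_prediction_rejected(self):
        df = pd.DataFrame({"g": ["a", "b"], "y": [1, 2]})
        with pytest.raises(ValueError, match="unseen"):
            build_design(pd.DataFrame({"g": ["c"]}),
                         [Covariate("g", kind="factor")],
                         factor_levels={"g": ("a", "b")})


class TestAicc:
    def test_formula(self):
        fit = GlmFit(beta=np.zeros(2), covariance=np.eye(2),
                     log_likelihood=-10.0, k=2, n=10, converged=True,
                     family="poisson", column_names=["a", "b"])
        assert aicc(fit) == pytest.approx(25.714286, abs=1e-5)

    def test_large_n_approaches_aic(self):
        fit = GlmFit(beta=np.zeros(3), covariance=np.eye(3),
                     log_likelihood=-50.0, k=3, n=10**8, converged=True,
                     family="poisson", column_names=list("abc"))
        assert aicc(fit) == pytest.approx(100 + 6, abs=1e-6)

    def test_undefined_when_n_too_small(self):
        fit = GlmFit(beta=np.zeros(4), covariance=np.eye(4),
                     log_likelihood=-1.0, k=4, n=5, converged=True,
                     family="poisson", column_names=list("abcd"))
        with pytest.raises(ValueError):
            aicc(fit)


class TestAllSubsets:
    def test_two_candidates_give_four_models(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"A": rng.normal(size=40), "B": rng.normal(size=40)})
        y = rng.poisson(3.0, size=40)
        spec = DesignSpec(response="site_richness",
                          covariates=(Covariate("A"), Covariate("B")))
        sel = all_subsets(spec, df, y)
        assert len(sel.table) == 4
        assert set(sel.table["subset"]) == {"", "A", "B", "A+B"}
        assert sel.table["daicc"].iloc[0] == 0.0

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(123)
        n = 500
        df = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n)})
        y = (rng.uniform(size=n) < expit(-0.3 + 1.0 * df["A"])).astype(float)
        spec = DesignSpec(response="detection",
                          covariates=(Covariate("A"), Covariate("B")))
        sel = all_subsets(spec, df, y.to_numpy())
        assert "A" in sel.best_subset

    def test_factors_enter_as_blocks(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"g": rng.choice(["a", "b", "c"], size=60)})
        y = rng.poisson(2.0, size=60)
        spec = DesignSpec(response="site_richness",
                          covariates=(Covariate("g", kind="factor"),))
        sel = all_subsets(spec, df, y)
        fit = sel.fits[("g",)]
        assert fit.k == 3  # intercept + two dummies, as one block


class TestPrediction:
    def test_intercept_only_poisson_delta_method(self):
        fit = GlmFit(beta=np.array([np.log(5.0)]),
                     covariance=np.array([[0.04]]), log_likelihood=0.0,
                     k=1, n=10, converged=True, family="poisson",
                     column_names=["Intercept"], covariates=())
        mean, se = predict_with_se(fit, pd.DataFrame(index=[0]))
        assert mean[0] == pytest.approx(5.0)
        assert se[0] == pytest.approx(5.0 * 0.2)

    def test_zero_variance_gives_zero_se(self):
        fit = GlmFit(beta=np.array([0.0]), covariance=np.array([[0.0]]),
                     log_likelihood=0.0, k=1, n=10, converged=True,
                     family="binomial", column_names=["Intercept"],
                     covariates=())
        mean, se = predict_with_se(fit, pd.DataFrame(index=[0]))
        assert mean[0] == pytest.approx(0.5)  # logistic at eta=0
        assert se[0] == 0.0

    def test_richness_prediction_positive(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"volume": rng.uniform(25, 80, size=50)})
        y = rng.poisson(2.0, size=50)
        spec = DesignSpec(response="site_richness",
                          covariates=(Covariate("volume"),))
        fit = fit_glm(spec, df, y)
        mean, _ = predict_with_se(
            fit, pd.DataFrame({"volume": [-100.0, 0.0, 500.0]}))
        assert np.all(mean > 0)  # log link keeps the mean positive


class TestDetectionCurves:
    def _fit(self, beta_rain=0.05):
        rng = np.random.default_rng(11)
        n = 600
        df = pd.DataFrame({
            "camera_rate": rng.uniform(0, 1, size=n),
            "rain_prev_day": rng.uniform(0, 30, size=n),
            "diet": rng.choice(["carnivore", "herbivore"], size=n),
        })
        eta = (-1.0 + 2.0 * df["camera_rate"] + beta_rain * df["rain_prev_day"]
               + 0.8 * (df["diet"] == "herbivore"))
        y = (rng.uniform(size=n) < expit(eta)).astype(float)
        spec = DesignSpec(response="detection", covariates=(
            Covariate("camera_rate"), Covariate("rain_prev_day"),
            Covariate("diet", kind="factor", reference="carnivore")))
        return fit_glm(spec, df, y.to_numpy())

    def test_monotone_in_camera_rate_when_beta_positive(self):
        fit = self._fit()
        curves = detection_curves(fit, ["carnivore"], "diet",
                                  camera_rate_grid=np.linspace(0, 1, 11))
        for _, grp in curves.groupby("rain"):
            assert np.all(np.diff(grp["mean"]) > 0)

    def test_rain_curve_dominates_when_beta_positive(self):
        fit = self._fit()
        curves = detection_curves(fit, ["herbivore"], "diet",
                                  camera_rate_grid=np.linspace(0, 1, 11))
        wet = curves[curves["rain"] == 30.0]["mean"].to_numpy()
        dry = curves[curves["rain"] == 0.0]["mean"].to_numpy()
        assert np.all(wet >= dry)

    def test_unknown_level_rejected(self):
        fit = self._fit()
        with pytest.raises(ValueError, match="absent"):
            detection_curves(fit, ["omnivore"], "diet",
                             camera_rate_grid=[0.0, 1.0])

    def test_recovers_true_curve_within_2se(self):
        # known-coefficient simulation: predicted curve vs truth
        fit = self._fit()
        grid = np.linspace(0.05, 0.95, 19)
        curves = detection_curves(fit, ["carnivore"], "diet",
                                  camera_rate_grid=grid)
        dry = curves[curves["rain"] == 0.0]
        truth = expit(-1.0 + 2.0 * grid)
        inside = np.abs(dry["mean"].to_numpy() - truth) <= 2 * dry["se"].to_numpy() + 0.02
        assert inside.mean() >= 0.9


class TestCameraRates:
    def _deployments(self):
        return [
            CameraDeployment(site_id="c1", year=2018, trap_days=90,
                             detections={"Alces alces": 9}),
            CameraDeployment(site_id="c2", year=2018, trap_days=100,
                             detections={"Alces alces": 30}),
        ]

    def test_single_camera_rate(self):
        rates = camera_rates(self._deployments(), {"e1": {"c1"}})
        assert rates.loc["Alces alces", "e1"] == pytest.approx(0.1)

    def test_mean_over_member_cameras(self):
        rates = camera_rates(self._deployments(), {"e1": {"c1", "c2"}})
        assert rates.loc["Alces alces", "e1"] == pytest.approx(0.2)

    def test_never_photographed_taxon_is_zero(self):
        deps = self._deployments()
        deps[0].detections["Gulo gulo"] = 0
        rates = camera_rates(deps, {"e1": {"c1", "c2"}})
        assert rates.loc["Gulo gulo", "e1"] == 0.0

    def test_empty_membership_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            camera_rates(self._deployments(), {"e1": set()})


class TestInvariances:
    def test_loglik_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = 80
            x = rng.normal(size=n)
            y = rng.poisson(np.exp(0.2 + 0.5 * x))
            X1 = np.column_stack([np.ones(n), x])
            X2 = np.column_stack([np.ones(n), 100.0 * x + 7.0])
            f1 = fit_glm_matrix(X1, y, "poisson")
            f2 = fit_glm_matrix(X2, y, "poisson")
            assert f1.log_likelihood == pytest.approx(f2.log_likelihood,
                                                      abs=1e-6)

    def test_irls_matches_nelder_mead_on_random_designs(self):
        from scipy.optimize import minimize
        from scipy.special import gammaln

        rng = np.random.default_rng(77)
        worst = 0.0
        for i in range(50):
            n, k = 60, int(rng.integers(1, 4))
            X = np.column_stack([np.ones(n)]
                                + [rng.normal(size=n) for _ in range(k)])
            beta = rng.normal(0, 0.5, size=k + 1)
            fam = "poisson" if i % 2 == 0 else "binomial"
            eta = X @ beta
            if fam == "poisson":
                y = rng.poisson(np.exp(eta)).astype(float)
            else:
                y = (rng.uniform(size=n) < expit(eta)).astype(float)
            fit = fit_glm_matrix(X, y, fam)
            if not fit.converged:
                continue

            def nll(b):
                e = X @ b
                if fam == "poisson":
                    return -np.sum(y * e - np.exp(e) - gammaln(y + 1))
                return -np.sum(np.where(y == 1, -np.log1p(np.exp(-e)),
                                        -np.log1p(np.exp(e))))

            res = minimize(nll, fit.beta + rng.normal(0, 0.1, size=k + 1),
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 20000, "maxfev": 20000})
            worst = max(worst, float(np.abs(res.x - fit.beta).max()))
        assert worst < 1e-6
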