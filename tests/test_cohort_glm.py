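"""Synthetic cohort calibration and GLM fitting/recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from mcpsim.cohort import (
    POPULATION_SUMMARY,
    CohortSizeError,
    CohortSpec,
    generate_cohort,
    require_fit_ready,
)
from mcpsim.glm_fit import (
    SingularDesignError,
    build_design,
    default_vital_models,
    fit_glm_irls,
    glm_diagnostics,
)
from mcpsim.vitals import PatientProfile, VitalSignsState, predict_vital


class TestGenerateCohort:
    def test_small_cohort_within_ranges(self):
        df = generate_cohort(CohortSpec(n=30, seed=1))
        assert len(df) == 30
        for var, (_, _, lo, hi) in POPULATION_SUMMARY.items():
            assert df[var].between(lo, hi).all()

    def test_female_fraction(self):
        df = generate_cohort(CohortSpec(n=8000, seed=2))
        frac = (df["gender"] == "female").mean()
        assert frac == pytest.approx(0.374, abs=3 * np.sqrt(0.374 * 0.626 / 8000))

    def test_deterministic_given_seed(self):
        a = generate_cohort(CohortSpec(n=100, seed=5))
        b = generate_cohort(CohortSpec(n=100, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_identity_correlation_gives_uncorrelated_sample(self):
        spec = CohortSpec(n=4000, seed=3)
        spec.correlation.loc[:, :] = np.eye(len(spec.correlation))
        df = generate_cohort(spec)
        corr = df[["hr", "rr", "gl", "sbp"]].corr().to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 4 / np.sqrt(4000)

    def test_infeasible_spec_rejected(self):
        targets = dict(POPULATION_SUMMARY)
        targets["hr"] = (30.0, 14.0, 40.0, 150.0)  # mean below the minimum
        with pytest.raises(ValueError, match="infeasible"):
            CohortSpec(n=100, seed=0, targets=targets)

    def test_group_labels_in_range(self):
        df = generate_cohort(CohortSpec(n=500, seed=4))
        assert set(df["group"]) <= {1, 2, 3, 4}

    def test_fit_floor_enforced(self):
        with pytest.raises(CohortSizeError, match="30"):
            require_fit_ready(generate_cohort(CohortSpec(n=29, seed=0)))
        require_fit_ready(generate_cohort(CohortSpec(n=30, seed=0)))


def _ig_deviance(y, mu):
    return np.sum((y - mu) ** 2 / (mu ** 2 * y))


def _gamma_deviance(y, mu):
    return 2 * np.sum(-np.log(y / mu) + (y - mu) / mu)


class TestFitGlmIrls:
    def test_intercept_only_gamma_closed_form(self):
        """Canonical-link score equation forces mu-hat = y-bar, so the
        intercept is 1/y-bar."""
        rng = np.random.default_rng(0)
        y = rng.gamma(5.0, 2.0, size=200)
        fit = fit_glm_irls("gamma", pd.DataFrame(index=range(200)), y)
        assert fit.params["const"] == pytest.approx(1.0 / y.mean(), rel=1e-8)

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame(np.random.default_rng(0).random((5, 8)))
        X.columns = [f"x{i}" for i in range(8)]
        with pytest.raises(ValueError, match="observations"):
            fit_glm_irls("gamma", X, np.ones(5) * 2.0)

    def test_nonpositive_response_rejected(self):
        X = pd.DataFrame({"x": np.arange(40, dtype=float)})
        y = np.ones(40)
        y[0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_glm_irls("gamma", X, y)

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.random(50)})
        X["b"] = 2 * X["a"]
        with pytest.raises(SingularDesignError, match="b|a"):
            fit_glm_irls("gamma", X, np.full(50, 3.0) + rng.random(50))

    @pytest.mark.parametrize("family", ["inverse-gaussian", "gamma"])
    def test_recovers_known_coefficients_within_3_se(self, family):
        rng = np.random.default_rng(42)
        n = 2000
        x1, x2 = rng.random(n), rng.random(n)
        beta = {"const": 0.01, "x1": 0.002, "x2": -0.001}
        eta = beta["const"] + beta["x1"] * x1 + beta["x2"] * x2
        mu = eta ** -0.5 if family == "inverse-gaussian" else 1.0 / eta
        if family == "inverse-gaussian":
            y = rng.wald(mu, 2e4)
        else:
            y = rng.gamma(50.0, mu / 50.0)
        fit = fit_glm_irls(family, pd.DataFrame({"x1": x1, "x2": x2}), y)
        for name, true in beta.items():
            assert abs(fit.params[name] - true) < 3 * fit.bse[name], (family, name)
        assert fit.converged

    @pytest.mark.parametrize("family,dev", [("inverse-gaussian", _ig_deviance), ("gamma", _gamma_deviance)])
    def test_irls_matches_direct_likelihood_maximization(self, family, dev):
        """On a tiny instance, IRLS and a direct numerical minimizer of the
        family deviance (equivalent to ML for fixed dispersion) agree to 1e-6."""
        rng = np.random.default_rng(7)
        n = 20
        x = rng.random(n)
        eta = 0.02 + 0.01 * x
        mu = eta ** -0.5 if family == "inverse-gaussian" else 1.0 / eta
        y = mu * (1 + 0.05 * rng.standard_normal(n))

        def inv_link(e):
            return e ** -0.5 if family == "inverse-gaussian" else 1.0 / e

        def objective(beta):
            e = beta[0] + beta[1] * x
            if np.any(e <= 0):
                return 1e12
            return dev(y, inv_link(e))

        direct = optimize.minimize(
            objective, x0=[0.03, 0.0], method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        fit = fit_glm_irls(family, pd.DataFrame({"x": x}), y)
        assert fit.params["const"] == pytest.approx(direct.x[0], abs=1e-6)
        assert fit.params["x"] == pytest.approx(direct.x[1], abs=1e-6)


class TestDiagnostics:
    def _fit(self, n=300, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.random(n)
        mu = 1.0 / (0.02 + 0.01 * x)
        y = rng.gamma(40.0, mu / 40.0)
        X = pd.DataFrame({"x": x})
        return fit_glm_irls("gamma", X, y), X, y

    def test_hat_values_sum_to_coefficient_count(self):
        fit, X, y = self._fit()
        diag = glm_diagnostics(fit, X, y, n_envelope=5)
        assert diag.leverage.sum() == pytest.approx(2.0, abs=1e-6)

    def test_outlier_dominates_cooks_distance(self):
        fit, X, y = self._fit()
        d0 = glm_diagnostics(fit, X, y, n_envelope=5).cooks_distance
        y2 = y.copy()
        y2[10] = y.max() * 5
        fit2 = fit_glm_irls("gamma", X, y2)
        d1 = glm_diagnostics(fit2, X, y2, n_envelope=5).cooks_distance
        assert d1[10] > d0[10]
        assert np.argmax(d1) == 10

    def test_well_specified_data_inside_envelope(self):
        fit, X, y = self._fit(seed=3)
        diag = glm_diagnostics(fit, X, y, n_envelope=60, seed=1)
        assert diag.fraction_in_envelope >= 0.9


class TestDefaultVitalModels:
    @pytest.fixture(scope="class")
    @staticmethod
    def cohort():
        return generate_cohort(CohortSpec(n=800, seed=11))

    def test_rr_design_has_ten_coefficients(self, cohort):
        X, _ = build_design(cohort, "rr", interactions=True)
        assert X.shape[1] == 9  # + intercept = 10 terms
        assert {"X52", "X53", "X54", "X6", "X7"} <= set(X.columns)

    def test_models_fitted_for_all_four_signs(self, cohort):
        specs = default_vital_models(cohort)
        assert set(specs) == {"hr", "rr", "sbp", "pt"}
        assert specs["rr"].family == "inverse-gaussian"
        assert specs["hr"].family == "gamma"

    def test_predictions_plausible_at_population_center(self, cohort):
        specs = default_vital_models(cohort)
        state = VitalSignsState(hr=87, rr=19, sbp=117, pt=37.3, gl=119)
        prof = PatientProfile(group=2)
        preds = {s: predict_vital(m, state, prof) for s, m in specs.items()}
        assert 60 <= preds["hr"] <= 110
        assert 10 <= preds["rr"] <= 30
        assert 95 <= preds["sbp"] <= 140
        assert 36 <= preds["pt"] <= 38.5

    def test_deterministic_given_cohort(self, cohort):
        assert default_vital_models(cohort) == default_vital_models(cohort.copy())

    def test_end_to_end_recovery_of_a_known_model(self):
        """A cohort whose rr is regenerated from a known inverse-Gaussian GLM
        is recovered by the packaged fit within fitting error."""
        rng = np.random.default_rng(23)
        cohort = generate_cohort(CohortSpec(n=2000, seed=23))
        X, _ = build_design(cohort, "rr", interactions=True)
        import statsmodels.api as sm

        truth = {"const": 0.004, "hr": -2e-5, "sbp": 1e-5, "pt": 0.0, "gl": -1e-5,
                 "X52": 0.0, "X53": 0.0, "X54": 0.0, "X6": 0.0, "X7": 0.0}
        eta = truth["const"] + sum(truth[c] * X[c] for c in X.columns)
        mu = np.abs(eta) ** -0.5
        cohort = cohort.copy()
        cohort["rr"] = rng.wald(mu, 5e4)
        fit = fit_glm_irls("inverse-gaussian", X, cohort["rr"])
        for name in ("const", "hr", "sbp", "gl"):
            assert abs(fit.params[name] - truth[name]) < 4 * fit.bse[name], name
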