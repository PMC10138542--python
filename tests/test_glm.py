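"""Gamma/log-link GLM: closed forms, screening, parameter recovery, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special

from airmort import glm
from airmort.glm import GLMResult, GLMSpec, build_design, fit_basic_model, fit_full_model, glm_predict
from airmort.preprocess import MinMaxScaling, ModelingDataset
from airmort.synthetic import COVARIATES


def _dataset_from_frame(frame: pd.DataFrame) -> ModelingDataset:
    scaling = MinMaxScaling.fit(frame, [*COVARIATES, "mortality_rate"])
    frame = frame.copy()
    frame["season"] = "dry"
    return ModelingDataset(records=frame, scaling=scaling)


def _gamma_glm_data(n=2000, seed=0, beta=None, shape=20.0):
    """Simulate rates from mu = exp(b0 + sum beta_k x_k) with gamma noise."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2007-01-01", periods=n, freq="D")
    frame = {"date": dates}
    frame["pm10"] = rng.uniform(15, 70, n)
    frame["no2"] = rng.uniform(20, 80, n)
    frame["so2"] = rng.uniform(1, 12, n)
    frame["temperature"] = rng.uniform(10, 28, n)
    frame["relative_humidity"] = rng.uniform(50, 95, n)
    frame["wind_speed"] = rng.uniform(0.5, 5, n)
    frame = pd.DataFrame(frame)
    beta = beta or {}
    eta = np.full(n, beta.get("intercept", 1.5))
    for name, b in beta.items():
        if name != "intercept":
            eta = eta + b * frame[name].to_numpy()
    mu = np.exp(eta)
    frame["mortality_rate"] = rng.gamma(shape=shape, scale=mu / shape)
    return _dataset_from_frame(frame), beta


class TestBasicModelScreening:
    def test_intercept_only_closed_form(self):
        # constant response: the fitted intercept is log of that constant
        ds, _ = _gamma_glm_data(n=200, seed=1)
        ds.records["mortality_rate"] = 5.0
        design = build_design(ds.records, ())
        result = glm._fit(design, ds.y, "m", GLMSpec(), ())
        assert result.table.loc[0, "beta"] == pytest.approx(np.log(5.0), abs=1e-8)

    def test_null_covariate_usually_excluded(self):
        # wind_speed has true effect 0; at alpha=0.05 it should be screened out
        # in the large majority of replicates (type-I error calibration)
        excluded = 0
        n_reps = 40
        for seed in range(n_reps):
            ds, _ = _gamma_glm_data(n=800, seed=seed, beta={"temperature": 0.01})
            spec = GLMSpec(basic_covariates=("temperature", "wind_speed"))
            res = fit_basic_model(ds, spec)
            if "wind_speed" not in res.retained_terms:
                excluded += 1
        assert excluded >= int(0.85 * n_reps)

    def test_true_effect_retained(self):
        ds, _ = _gamma_glm_data(n=2000, seed=3, beta={"temperature": 0.02})
        spec = GLMSpec(basic_covariates=("temperature", "wind_speed"))
        res = fit_basic_model(ds, spec)
        assert "temperature" in res.retained_terms

    def test_zero_response_reported_with_hint(self):
        ds, _ = _gamma_glm_data(n=100, seed=4)
        ds.records.loc[0, "mortality_rate"] = 0.0
        with pytest.raises(ValueError, match="offset"):
            fit_basic_model(ds, GLMSpec(basic_covariates=("temperature",)))


class TestFullModel:
    def test_parameter_recovery_single_run(self):
        true = {"intercept": 1.5, "pm10": 0.002, "no2": 0.001, "so2": -0.003}
        ds, _ = _gamma_glm_data(n=5000, seed=5, beta=true)
        res = fit_full_model(ds, GLMSpec(basic_covariates=()), retained_basic_terms=())
        table = res.table.set_index("term")
        for name in ("pm10", "no2", "so2"):
            est = table.loc[name, "beta"]
            se = (table.loc[name, "ci_high"] - table.loc[name, "ci_low"]) / (2 * 1.96)
            assert abs(est - true[name]) < 3 * se

    def test_ci_brackets_point_estimate(self):
        ds, _ = _gamma_glm_data(n=500, seed=6, beta={"pm10": 0.002})
        res = fit_full_model(ds, retained_basic_terms=("temperature",))
        assert (res.table["ci_low"] <= res.table["beta"]).all()
        assert (res.table["beta"] <= res.table["ci_high"]).all()

    def test_duplicated_covariate_rank_deficiency(self):
        ds, _ = _gamma_glm_data(n=300, seed=7)
        ds.records["pm10"] = ds.records["no2"]  # exact collinearity
        with pytest.raises(ValueError, match="rank deficient"):
            fit_full_model(ds, retained_basic_terms=())

    def test_irls_matches_direct_likelihood_optimization(self):
        # independent route: maximize the gamma log-likelihood (profile shape)
        ds, _ = _gamma_glm_data(n=200, seed=8, beta={"pm10": 0.002, "so2": -0.004})
        res = fit_full_model(ds, GLMSpec(basic_covariates=()), retained_basic_terms=())
        design = build_design(ds.records, ("pm10", "no2", "so2")).to_numpy()
        y = ds.y

        def negll(params):
            beta, log_shape = params[:-1], params[-1]
            k = np.exp(log_shape)
            mu = np.exp(design @ beta)
            return -np.sum(
                k * np.log(k / mu) + (k - 1) * np.log(y) - k * y / mu - special.gammaln(k)
            )

        beta0 = np.concatenate([res.table["beta"].to_numpy() * 0.9, [1.0]])
        opt = optimize.minimize(negll, beta0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
        np.testing.assert_allclose(opt.x[:-1], res.table["beta"].to_numpy(), atol=1e-5)

    def test_calendar_terms_expand_to_dummies(self):
        ds, _ = _gamma_glm_data(n=400, seed=9)
        design = build_design(ds.records, ("month", "day_of_week", "year"))
        month_cols = [c for c in design.columns if c.startswith("month[")]
        dow_cols = [c for c in design.columns if c.startswith("day_of_week[")]
        assert len(month_cols) == 11 and len(dow_cols) == 6
        assert "year" in design.columns


class TestPrediction:
    def test_intercept_only_prediction(self):
        # published-scale check: exp(1.626) = 5.084
        assert np.exp(1.626) == pytest.approx(5.084, abs=0.001)

    def test_zero_betas_predict_one(self):
        ds, _ = _gamma_glm_data(n=50, seed=10)
        res = fit_full_model(ds, GLMSpec(basic_covariates=()), retained_basic_terms=())
        res.table["beta"] = 0.0
        mu = glm_predict(res, ds.records)
        np.testing.assert_allclose(mu, 1.0)

    def test_predictions_positive_and_monotone(self):
        ds, _ = _gamma_glm_data(n=1000, seed=11, beta={"pm10": 0.003})
        res = fit_full_model(ds, GLMSpec(basic_covariates=()), retained_basic_terms=())
        mu = glm_predict(res, ds.records)
        assert (mu > 0).all()
        bumped = ds.records.copy()
        bumped["pm10"] += 10.0
        beta_pm10 = res.table.set_index("term").loc["pm10", "beta"]
        mu2 = glm_predict(res, bumped)
        if beta_pm10 > 0:
            assert (mu2 > mu).all()
        else:
            assert (mu2 < mu).all()
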