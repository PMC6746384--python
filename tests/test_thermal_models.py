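import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import make_null_dataset, true_label_frame
from lekaccel.activity_aggregation import (build_burst_table,
                                           build_daily_table,
                                           hourly_proportions, qualify_days)
from lekaccel.additive import (AdditiveModelFit, NonConvergenceError,
                               SplineBasis, fit_additive_model)
from lekaccel.thermal_response_models import (PartialEffect, PredictiveError,
                                              cv_predictive_error,
                                              fit_daily_model,
                                              fit_hourly_model,
                                              partial_effects)


def _daily_frame(n=120, n_birds=6, slope=0.0, noise=0.02, seed=0,
                 intercept=0.4):
    rng = np.random.default_rng(seed)
    temp = rng.uniform(10, 26, n)
    jdate = rng.integers(100, 150, n).astype(float)
    bird = rng.choice([f"bird_{i}" for i in range(n_birds)], n)
    y = intercept + slope * (temp - 18) + rng.normal(0, noise, n)
    return pd.DataFrame({"bird_id": bird, "jdate": jdate,
                         "daytime_mean_temp": temp,
                         "display_activity": np.clip(y, 0, 1)})


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------

class TestSplineBasis:
    def test_degenerate_covariate_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            SplineBasis.build("x", np.full(10, 3.0))

    def test_sum_to_zero_constraint(self):
        x = np.linspace(0, 1, 50)
        basis = SplineBasis.build("x", x, k=4)
        assert basis.design(x).mean(axis=0) == pytest.approx(np.zeros(3), abs=1e-12)

    def test_clamp_extrapolation_is_flat(self):
        x = np.linspace(0, 1, 50)
        basis = SplineBasis.build("x", x, k=4)
        inside = basis.design(np.array([1.0]))
        outside = basis.design(np.array([2.5]), extrapolation="clamp")
        assert np.allclose(inside, outside)

    def test_linear_extrapolation_continues_slope(self):
        x = np.linspace(0, 1, 50)
        basis = SplineBasis.build("x", x, k=4)
        b1 = basis.design(np.array([1.0]), extrapolation="linear")
        b2 = basis.design(np.array([2.0]), extrapolation="linear")
        b3 = basis.design(np.array([3.0]), extrapolation="linear")
        assert np.allclose(b3 - b2, b2 - b1)


class TestFitAdditiveModel:
    def test_gaussian_recovers_linear_signal(self):
        df = _daily_frame(slope=-0.02, noise=0.01, seed=1)
        fit = fit_additive_model(df, "display_activity",
                                 ["daytime_mean_temp", "jdate"], "gaussian",
                                 random_intercept="bird_id")
        grid = np.linspace(11, 25, 30)
        eff, _ = fit.term_effect("daytime_mean_temp", grid)
        slope = np.polyfit(grid, eff, 1)[0]
        assert slope == pytest.approx(-0.02, abs=0.005)

    def test_binomial_requires_01_response(self):
        df = _daily_frame()
        df["display_activity"] = 0.5
        with pytest.raises(ValueError, match="0/1"):
            fit_additive_model(df, "display_activity", ["jdate"], "binomial")

    def test_unknown_family(self):
        with pytest.raises(ValueError, match="family"):
            fit_additive_model(_daily_frame(), "display_activity", ["jdate"],
                               "poisson")

    def test_increasing_k_never_decreases_likelihood(self):
        # monotone flexibility at (effectively) zero penalty
        df = _daily_frame(slope=-0.03, noise=0.03, seed=2)
        devs = []
        for k in (3, 4, 5):
            fit = fit_additive_model(df, "display_activity",
                                     ["daytime_mean_temp"], "gaussian",
                                     k=k, lambdas=[1e-10])
            devs.append(fit.deviance)
        assert devs[0] >= devs[1] - 1e-9
        assert devs[1] >= devs[2] - 1e-9

    def test_binomial_fitted_monotone_in_monotone_effect(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 800)
        y = (rng.random(800) < expit(-2 + 4 * x)).astype(float)
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_additive_model(df, "y", ["x"], "binomial")
        grid = np.linspace(0.02, 0.98, 40)
        pred = fit.predict({"x": grid})
        assert np.all(np.diff(pred) > -1e-6)

    def test_single_level_random_intercept_dropped_with_warning(self):
        df = _daily_frame(n_birds=1)
        with pytest.warns(UserWarning, match="random intercept dropped"):
            fit = fit_additive_model(df, "display_activity",
                                     ["daytime_mean_temp"], "gaussian",
                                     random_intercept="bird_id")
        assert all(t.kind == "smooth" for t in fit.terms)

    def test_edf_within_basis_bounds(self, hourly_fit):
        for t in hourly_fit.smooth_terms:
            assert 0.5 <= t.edf <= 3.0 + 1e-6  # k=4 minus constraint

    def test_report_is_jsonable(self, daily_fit):
        import json

        text = json.dumps(daily_fit.report())
        assert "edf" in text


# ---------------------------------------------------------------------------
# study models
# ---------------------------------------------------------------------------

class TestHourlyModel:
    def test_requires_columns(self):
        with pytest.raises(ValueError, match="missing required columns"):
            fit_hourly_model(pd.DataFrame({"display": [0, 1]}))

    def test_null_truth_recovers_flat_effects(self):
        ds = make_null_dataset(seed=21, n_birds=6)
        bt = build_burst_table(true_label_frame(ds), ds.schedules)
        fit = fit_hourly_model(bt)
        for effect in partial_effects(fit):
            assert np.max(np.abs(effect.effect)) < 0.25
        for t in fit.smooth_terms:
            assert t.edf < 2.0

    def test_default_study_temperature_shape(self, hourly_fit):
        # decline 4 -> 20 degC, near-flat 20 -> 30, per the study
        (pe,) = partial_effects(hourly_fit, ["temp_c"], grid_size=200)
        lo, hi = pe.grid.min(), pe.grid.max()

        def val(t):
            return np.interp(t, pe.grid, pe.effect)

        t0, t1 = max(6.0, lo), min(20.0, hi)
        assert val(t0) - val(t1) > 0.8
        if hi > 24:
            drop_plateau = abs(val(20.0) - val(min(hi, 30.0)))
            assert drop_plateau < 0.6

    def test_default_study_morning_exceeds_midday(self, hourly_fit):
        (pe,) = partial_effects(hourly_fit, ["hour_frac"], grid_size=100)
        morning = pe.effect[(pe.grid >= 5) & (pe.grid < 8)].mean()
        midday = pe.effect[(pe.grid >= 11) & (pe.grid < 16)].mean()
        assert morning > midday + 0.2

    def test_temperature_recovery_against_truth(self, hourly_fit, default_study):
        (pe,) = partial_effects(hourly_fit, ["temp_c"], grid_size=100)
        truth = default_study.truth["f_temp"]
        true_vals = np.interp(pe.grid, truth["grid"], truth["value"])
        assert np.corrcoef(pe.effect, true_vals)[0, 1] >= 0.9


class TestDailyModel:
    def test_constant_response_is_flat(self):
        df = _daily_frame(noise=0.0)
        df["display_activity"] = 0.37
        fit = fit_daily_model(df)
        assert fit.scale == pytest.approx(0.0, abs=1e-10)
        for effect in partial_effects(fit):
            assert np.max(np.abs(effect.effect)) < 1e-5

    def test_known_slope_sign_recovered(self):
        hits = 0
        for seed in range(5):
            df = _daily_frame(slope=-0.015, noise=0.03, seed=seed)
            fit = fit_daily_model(df)
            grid = np.linspace(12, 24, 20)
            eff, _ = fit.term_effect("daytime_mean_temp", grid)
            hits += np.polyfit(grid, eff, 1)[0] < 0
        assert hits >= 4

    def test_too_few_rows(self):
        with pytest.raises(ValueError, match=">= 10"):
            fit_daily_model(_daily_frame(n=5))

    def test_default_study_temperature_effect_decreases(self, daily_fit):
        (pe,) = partial_effects(daily_fit, ["daytime_mean_temp"], grid_size=60)
        # monotonically decreasing over the observed daily-mean range
        assert np.all(np.diff(pe.effect) < 1e-3)
        assert pe.effect[0] - pe.effect[-1] > 0.05

    def test_default_study_date_effect_unimodal(self, daily_fit):
        (pe,) = partial_effects(daily_fit, ["jdate"], grid_size=80)
        peak = np.argmax(pe.effect)
        assert 0 < peak < len(pe.grid) - 1
        assert np.all(np.diff(pe.effect[: peak + 1]) > -1e-6)
        assert np.all(np.diff(pe.effect[peak:]) < 1e-6)


# ---------------------------------------------------------------------------
# partial effects
# ---------------------------------------------------------------------------

class TestPartialEffects:
    def test_unknown_term(self, daily_fit):
        with pytest.raises(KeyError, match="unknown term"):
            partial_effects(daily_fit, ["nope"])

    def test_band_contains_estimate_and_round_trips(self, daily_fit):
        for effect in partial_effects(daily_fit):
            assert np.all(effect.lower <= effect.effect)
            assert np.all(effect.effect <= effect.upper)
            back = PartialEffect.from_frame(effect.to_frame())
            assert np.array_equal(back.effect, effect.effect)
            assert np.array_equal(back.lower, effect.lower)

    def test_band_validation(self):
        with pytest.raises(ValueError, match="band"):
            PartialEffect("x", np.arange(3.0), np.ones(3), np.full(3, 2.0),
                          np.full(3, 3.0))

    def test_null_truth_band_covers_zero(self):
        # pointwise 95% bands should cover the flat truth at >= ~95% of
        # grid points on average over replicates
        # pointwise misses are perfectly correlated within a replicate, so
        # the replicate average needs a decent number of fits
        rates = []
        for seed in range(16):
            df = _daily_frame(slope=0.0, noise=0.05, seed=100 + seed)
            fit = fit_daily_model(df)
            (pe,) = partial_effects(fit, ["daytime_mean_temp"], grid_size=50)
            rates.append(np.mean((pe.lower <= 0) & (0 <= pe.upper)))
        assert np.mean(rates) >= 0.90


# ---------------------------------------------------------------------------
# cross-validated predictive error
# ---------------------------------------------------------------------------

class _StubFit:
    """Minimal fit object for hand-computed CV metric checks."""

    def __init__(self, family, response, predict_fn):
        self.family = family
        self.response = response
        self.terms = []
        self._fn = predict_fn

    def predict(self, data, include_random=True):
        return self._fn(data)


class TestCVPredictiveError:
    def test_noiseless_binary_error_rate_zero(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 300)
        df = pd.DataFrame({"x": x, "y": (x > 0).astype(float)})

        def fit_fn(train):
            return _StubFit("binomial", "y",
                            lambda d: (np.asarray(d["x"]) > 0).astype(float))

        err = cv_predictive_error(df, fit_fn, k=10, seed=1)
        assert err.metric == "error_rate"
        assert err.mean == pytest.approx(0.0)

    def test_pure_noise_matches_majority_baseline(self):
        # analytic baseline: always-predict-majority errs 100*min(p, 1-p)
        rng = np.random.default_rng(1)
        p = 0.3
        df = pd.DataFrame({"x": rng.uniform(size=3000),
                           "y": (rng.random(3000) < p).astype(float)})

        def fit_fn(train):
            maj = float(train["y"].mean() >= 0.5)
            return _StubFit("binomial", "y",
                            lambda d: np.full(len(d["x"]), maj))

        err = cv_predictive_error(df, fit_fn, k=10, seed=2)
        assert err.mean == pytest.approx(100 * min(p, 1 - p), abs=3.0)

    def test_half_range_shift_gives_nrmse_half(self):
        # hand computation: constant shift of half the response range
        y = np.linspace(0.0, 1.0, 200)
        df = pd.DataFrame({"x": np.zeros(200), "y": y, "_y_true": y})

        def fit_fn(train):  # predictions shifted by half the response range
            return _StubFit("gaussian", "y", lambda d: d["_y_true"] + 0.5)
        err = cv_predictive_error(df, fit_fn, k=10, seed=3)
        assert err.metric == "nrmse"
        assert err.mean == pytest.approx(0.5, abs=1e-9)
        assert err.sd == pytest.approx(0.0, abs=1e-9)

    def test_row_order_invariance_of_means(self, study_tables):
        _, dt = study_tables
        fit_fn = lambda t: fit_daily_model(t)
        e1 = cv_predictive_error(dt, fit_fn, k=5, seed=4)
        shuffled = dt.sample(frac=1.0, random_state=9).reset_index(drop=True)
        e2 = cv_predictive_error(shuffled, fit_fn, k=5, seed=4)
        assert e2.mean == pytest.approx(e1.mean, abs=3 * (e1.sd + e2.sd + 0.01))

    def test_table_too_small(self):
        with pytest.raises(ValueError, match="folds"):
            cv_predictive_error(_daily_frame(n=5), fit_daily_model, k=10)

    def test_metric_name_validated(self):
        with pytest.raises(ValueError, match="metric"):
            PredictiveError("rmse", 1.0, 0.1, (1.0,))

    def test_daily_model_nrmse_reasonable(self, study_tables):
        _, dt = study_tables
        err = cv_predictive_error(dt, lambda t: fit_daily_model(t), k=10, seed=5)
        assert err.metric == "nrmse"
        assert 0.0 < err.mean < 1.0
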