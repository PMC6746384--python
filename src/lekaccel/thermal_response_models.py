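"""The two smooth additive mixed models of display behaviour vs temperature.

* Hourly (burst-level) model: display occurrence (0/1) ~ s(temperature) +
  s(time of day) + s(Julian date) + bird random intercept, binomial.
* Daily model: display activity (proportion) ~ s(daytime mean temperature) +
  s(Julian date) + bird random intercept, gaussian.

Both use penalized cubic-spline smooths with basis dimension k=4 and report
per-term effective degrees of freedom, approximate test statistics, and
pointwise 95% confidence bands.  Predictive error is estimated by 10-fold
cross-validation: percentage of misclassifications at a 0.5 threshold for
the binomial model, RMSE divided by the observed response range (NRMSE) for
the gaussian model.  Smoothing parameters are re-estimated in every CV fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .accel_io import get_logger
from .additive import AdditiveModelFit, NonConvergenceError, fit_additive_model
from .synthetic_data import substream

__all__ = [
    "PartialEffect",
    "PredictiveError",
    "cv_predictive_error",
    "fit_daily_model",
    "fit_hourly_model",
    "partial_effects",
]

HOURLY_TERMS = ("temp_c", "hour_frac", "jdate")
DAILY_TERMS = ("daytime_mean_temp", "jdate")


@dataclass(frozen=True)
class PartialEffect:
    """A centered smooth-term curve with a pointwise 95% band
    (linear-predictor scale)."""

    term: str
    grid: np.ndarray
    effect: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        if not (np.all(self.lower <= self.effect + 1e-12)
                and np.all(self.effect <= self.upper + 1e-12)):
            raise ValueError("confidence band must contain the point estimate")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": self.term, "grid": self.grid, "effect": self.effect,
            "lower": self.lower, "upper": self.upper,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PartialEffect":
        return cls(term=str(df["term"].iloc[0]),
                   grid=df["grid"].to_numpy(float),
                   effect=df["effect"].to_numpy(float),
                   lower=df["lower"].to_numpy(float),
                   upper=df["upper"].to_numpy(float))


@dataclass(frozen=True)
class PredictiveError:
    """Cross-validated predictive error: mean +- sd over folds."""

    metric: str                 # "error_rate" (percent) | "nrmse"
    mean: float
    sd: float
    per_fold: tuple

    def __post_init__(self) -> None:
        if self.metric not in ("error_rate", "nrmse"):
            raise ValueError(f"unknown metric {self.metric!r}")


def fit_hourly_model(burst_table: pd.DataFrame, *, k: int = 4,
                     extrapolation: str = "clamp",
                     lambdas: Sequence[float] | None = None) -> AdditiveModelFit:
    """Binomial GAMM of per-burst display occurrence.

    Requires columns display (0/1), temp_c, hour_frac, jdate, bird_id.
    With a single bird the random intercept is dropped with a warning.
    """
    _check_columns(burst_table, ("display",) + HOURLY_TERMS + ("bird_id",))
    n_birds = burst_table["bird_id"].nunique()
    fit = fit_additive_model(
        burst_table, "display", HOURLY_TERMS, "binomial",
        random_intercept="bird_id" if n_birds >= 2 else None,
        k=k, lambdas=lambdas, extrapolation=extrapolation)
    get_logger("model").info(
        "hourly model: n=%d edf=%.2f deviance=%.1f", fit.n, fit.edf_total, fit.deviance)
    return fit


def fit_daily_model(daily_table: pd.DataFrame, *, k: int = 4,
                    extrapolation: str = "clamp",
                    lambdas: Sequence[float] | None = None) -> AdditiveModelFit:
    """Gaussian GAMM of daily display activity.

    Requires columns display_activity, daytime_mean_temp, jdate, bird_id.
    """
    _check_columns(daily_table, ("display_activity",) + DAILY_TERMS + ("bird_id",))
    if len(daily_table) < 10:
        raise ValueError(f"daily table has {len(daily_table)} rows; need >= 10")
    n_birds = daily_table["bird_id"].nunique()
    fit = fit_additive_model(
        daily_table, "display_activity", DAILY_TERMS, "gaussian",
        random_intercept="bird_id" if n_birds >= 2 else None,
        k=k, lambdas=lambdas, extrapolation=extrapolation)
    get_logger("model").info(
        "daily model: n=%d edf=%.2f scale=%.4g", fit.n, fit.edf_total, fit.scale)
    return fit


def partial_effects(fit: AdditiveModelFit, terms: Sequence[str] | None = None,
                    grid_size: int = 100) -> list[PartialEffect]:
    """Centered partial-effect curves with pointwise 95% bands.

    Grids span the observed covariate range recorded in each smooth's basis.
    """
    if terms is None:
        terms = [t.name for t in fit.smooth_terms]
    out = []
    for name in terms:
        t = fit.term(name)  # raises KeyError for unknown terms
        grid = np.linspace(t.basis.xmin, t.basis.xmax, grid_size)
        effect, se = fit.term_effect(name, grid)
        out.append(PartialEffect(term=name, grid=grid, effect=effect,
                                 lower=effect - 1.96 * se,
                                 upper=effect + 1.96 * se))
    return out


def cv_predictive_error(table: pd.DataFrame,
                        fit_fn: Callable[[pd.DataFrame], AdditiveModelFit],
                        *, k: int = 10, seed: int = 0,
                        threshold: float = 0.5) -> PredictiveError:
    """k-fold cross-validated predictive error of a model specification.

    Rows are split into k near-equal random parts; the model (including its
    smoothing parameters) is refit on k-1 parts and predicts the held-out
    part.  Binomial fits score the percentage of misclassifications at
    ``threshold``; gaussian fits score RMSE divided by the observed range of
    the response over the full table.  Folds whose refit fails are skipped
    and reported.
    """
    n = len(table)
    if n < k:
        raise ValueError(f"table of {n} rows cannot form {k} folds")
    rng = substream(seed, "cv_folds")
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    probe = fit_fn(table.iloc[np.sort(np.concatenate(folds[1:]))])
    family = probe.family
    resp = probe.response
    y_all = table[resp].to_numpy(float)
    resp_range = float(y_all.max() - y_all.min())

    scores, skipped = [], 0
    log = get_logger("model")
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx)
        train, test = table.iloc[np.sort(train_idx)], table.iloc[np.sort(test_idx)]
        try:
            fit = fit_fn(train) if i > 0 else probe
        except (NonConvergenceError, np.linalg.LinAlgError) as exc:
            log.warning("CV fold %d refit failed (%s); fold skipped", i, exc)
            skipped += 1
            continue
        known = set(train["bird_id"]) if "bird_id" in train.columns else set()
        pred = _predict_mixed(fit, test, known)
        y = test[resp].to_numpy(float)
        if family == "binomial":
            scores.append(100.0 * float(np.mean((pred >= threshold) != (y >= 0.5))))
        else:
            rmse = float(np.sqrt(np.mean((pred - y) ** 2)))
            scores.append(rmse / resp_range if resp_range > 0 else 0.0)
    if not scores:
        raise NonConvergenceError("all CV folds failed to refit")
    metric = "error_rate" if family == "binomial" else "nrmse"
    return PredictiveError(metric=metric, mean=float(np.mean(scores)),
                           sd=float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                           per_fold=tuple(scores))


def _predict_mixed(fit: AdditiveModelFit, test: pd.DataFrame,
                   known_birds: set) -> np.ndarray:
    """Predict held-out rows, using the bird intercept only for birds seen
    in training (others at the population level)."""
    has_re = any(t.kind == "random" for t in fit.terms)
    if not has_re or not known_birds:
        return fit.predict(test, include_random=False)
    seen = test["bird_id"].isin(known_birds).to_numpy()
    pred = fit.predict(test, include_random=False)
    if seen.any():
        pred_re = fit.predict(test, include_random=True)
        pred[seen] = pred_re[seen]
    return pred


def _check_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"table missing required columns: {missing}")
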