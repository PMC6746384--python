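"""Warming-scenario projection of daily display activity.

For each temperature increment, every observed bird-day is predicted twice
from the fitted daily model — at its observed daytime mean temperature and
at temperature + delta — holding Julian date fixed and the bird random
intercept at zero (population level).  The reported decrease is the mean
difference in predicted activity, in absolute percentage points (relative
percent change is emitted alongside, since the two readings of "a decrease
of X%" cannot be distinguished).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .accel_io import get_logger
from .additive import AdditiveModelFit

__all__ = ["ScenarioResult", "project", "scenarios_to_frame"]


@dataclass(frozen=True)
class ScenarioResult:
    """Projected change in mean daily display activity under +delta_t degC."""

    delta_t: float
    baseline_activity: float       # mean predicted activity, observed temps
    shifted_activity: float        # mean predicted activity, temps + delta
    decrease_points: float         # 100 * (baseline - shifted)
    decrease_relative: float       # 100 * (baseline - shifted) / baseline
    ci_lower: float                # 95% CI on decrease_points
    ci_upper: float
    extrapolated: bool             # any shifted temperature beyond fitted range

    def __post_init__(self) -> None:
        expected = 100.0 * (self.baseline_activity - self.shifted_activity)
        if abs(self.decrease_points - expected) > 1e-9:
            raise ValueError("decrease_points must equal 100*(baseline - shifted)")


def project(fit: AdditiveModelFit, daily_table: pd.DataFrame,
            deltas: Sequence[float]) -> list[ScenarioResult]:
    """Project mean display activity under uniform temperature increases.

    ``fit`` must be the gaussian daily model (response display_activity,
    smooths of daytime_mean_temp and jdate).  Deltas must be >= 0; shifts
    beyond the fitted temperature range are flagged and handled per the
    fit's extrapolation policy (clamped by default).
    """
    if any(d < 0 for d in deltas):
        raise ValueError(f"deltas must be >= 0, got {list(deltas)}")
    if fit.family != "gaussian":
        raise ValueError("projection requires the gaussian daily model")
    temp_term = fit.term("daytime_mean_temp")
    tmax = temp_term.basis.xmax
    log = get_logger("project")

    base_data = {
        "daytime_mean_temp": daily_table["daytime_mean_temp"].to_numpy(float),
        "jdate": daily_table["jdate"].to_numpy(float),
    }
    n = len(daily_table)
    baseline = fit.predict(base_data, include_random=False)

    results = []
    for d in deltas:
        shifted_temp = base_data["daytime_mean_temp"] + d
        extrapolated = bool(np.any(shifted_temp > tmax))
        if extrapolated:
            log.warning("delta=+%.1f degC pushes %d/%d days beyond the fitted "
                        "range (max %.1f degC); %s extrapolation", d,
                        int(np.sum(shifted_temp > tmax)), n, tmax,
                        fit.extrapolation)
        shifted = fit.predict({"daytime_mean_temp": shifted_temp,
                               "jdate": base_data["jdate"]},
                              include_random=False)
        # CI of the mean difference from the coefficient covariance: the
        # difference depends only on the temperature-smooth block.
        Xb = temp_term.basis.design(base_data["daytime_mean_temp"],
                                    extrapolation=fit.extrapolation)
        Xs = temp_term.basis.design(shifted_temp, extrapolation=fit.extrapolation)
        contrast = (Xb - Xs).mean(axis=0)
        V = fit.cov[np.ix_(temp_term.cols, temp_term.cols)]
        se_points = 100.0 * float(np.sqrt(max(contrast @ V @ contrast, 0.0)))

        base_mean = float(baseline.mean())
        shift_mean = float(shifted.mean())
        dec = 100.0 * (base_mean - shift_mean)
        results.append(ScenarioResult(
            delta_t=float(d),
            baseline_activity=base_mean,
            shifted_activity=shift_mean,
            decrease_points=dec,
            decrease_relative=100.0 * (base_mean - shift_mean) / base_mean
            if base_mean != 0 else np.nan,
            ci_lower=dec - 1.96 * se_points,
            ci_upper=dec + 1.96 * se_points,
            extrapolated=extrapolated,
        ))
    return results


def scenarios_to_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
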