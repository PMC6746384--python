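"""Configuration for the display-behaviour analysis pipeline.

Every study constant (daylight window, filter thresholds, smoothing basis
dimension, scenario deltas, simulator calibration) lives here, never
hard-coded in pipeline stages.  A run is configured by a YAML file that is
deep-merged over :data:`DEFAULT_CONFIG`; :func:`validate_config` fail-fasts
with the offending key path before any stage executes.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "AXES",
    "DEFAULT_CONFIG",
    "ConfigError",
    "PipelineConfig",
    "deep_merge",
    "load_config",
    "save_config",
    "validate_config",
]

#: Body-frame axis order used throughout the package.
AXES = ("sway", "surge", "heave")


class ConfigError(ValueError):
    """Raised when a configuration is missing keys or violates invariants."""


# Environment defaults produced by synthetic_data.calibrate_environment
# (grid search against daytime mean 18 degC, corr(T, hour)=0.51,
# corr(T, date)=0.16); see that function's docstring.
_ENVIRONMENT_DEFAULTS = {
    "daytime_mean": 18.0,
    "seasonal_slope": 0.035,
    "diurnal_amplitude": 3.84,
    "diurnal_peak_hour": 15.5,
    "site_offset_sd": 1.2,
    "hourly_noise_sd": 1.6,
    "daily_anomaly_sd": 2.4,
}

# Piecewise-linear response functions on the logit scale.  Shapes follow the
# fitted partial effects: temperature effect declines steeply from 4 to
# 20 degC, plateaus 20-30 degC, declines after; hour effect is elevated
# 5:00-10:00 then flat through daylight; date effect rises from day 107 to a
# peak at day 124 then declines.  The intercept is tuned by
# synthetic_data.tune_intercept so daylight display prevalence is ~41.5%.
_RESPONSE_DEFAULTS = {
    "intercept": -0.2086,
    "bird_sd": 0.5,
    "temp_knots": [0.0, 4.0, 20.0, 30.0, 40.0],
    "temp_values": [1.3, 1.3, -0.75, -0.85, -2.2],
    "hour_knots": [0.0, 4.0, 5.0, 10.0, 21.0, 24.0],
    "hour_values": [-2.5, -2.5, 1.1, 0.0, 0.0, -2.5],
    "date_knots": [91.0, 107.0, 124.0, 152.0],
    "date_values": [-0.30, -0.15, 0.42, -0.45],
    "nondisplay_mixture": {
        "rest": 0.45,
        "forage": 0.35,
        "alert": 0.15,
        "flight": 0.05,
    },
}

# Per-class acceleration signatures, axis order (sway, surge, heave), in g.
# Display matches the video-validated signature; the rest are invented but
# plausible postures, with "alert" deliberately close to display.
_SIGNATURE_DEFAULTS = {
    "display": {
        "static_mean": [-0.03, 0.81, 0.60],
        "static_sd_between": [0.029, 0.0885, 0.0985],
        "dynamic_sd_within": [0.05, 0.08, 0.08],
    },
    "rest": {
        "static_mean": [0.00, 0.15, 0.95],
        "static_sd_between": [0.02, 0.05, 0.05],
        "dynamic_sd_within": [0.01, 0.012, 0.012],
    },
    "forage": {
        "static_mean": [0.00, 0.45, 0.85],
        "static_sd_between": [0.04, 0.10, 0.08],
        "dynamic_sd_within": [0.06, 0.09, 0.08],
    },
    "alert": {
        "static_mean": [-0.02, 0.72, 0.55],
        "static_sd_between": [0.03, 0.09, 0.10],
        "dynamic_sd_within": [0.018, 0.025, 0.025],
    },
    "flight": {
        "static_mean": [0.00, 0.30, 1.10],
        "static_sd_between": [0.05, 0.20, 0.25],
        "dynamic_sd_within": [0.35, 0.45, 0.60],
    },
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 20150401,
    "study": {
        "daylight_start_hour": 5,
        "daylight_end_hour": 21,          # [5, 21): 16 daylight hours
        "post_tag_exclusion_days": 2,
        "training_fraction": 0.10,
        "label_window_s": 7,
        "cv_folds": 10,
        "smooth_basis_k": 4,
        "min_bursts_per_hour": 2,
        "min_hours_per_day": 11,
        "scenario_deltas": [1, 2, 3, 4, 5, 6, 7],
        "decision_threshold": 0.5,
        "extrapolation": "clamp",         # clamp | linear
        "group_cv_by_bird": False,
        "classifier_families": ["random_forest", "decision_tree", "knn", "linear_svm"],
        "forest_size": 500,
        "knn_neighbors": 5,
        "smoothing_criterion": "gcv",
    },
    "simulation": {
        "n_birds": 17,
        "n_sites": 5,
        "season_start_day": 91,
        "season_end_day": 151,
        "start_day_min": 95,
        "start_day_max": 138,
        "duration_mean": 12.8,
        "duration_sd": 7.2,
        "duration_min": 2,
        "duration_max": 25,
        "burst_intervals": [10, 20],
        "n_samples": 10,
        "missing_prob": 0.10,
        "year": 2015,
        "environment": _ENVIRONMENT_DEFAULTS,
        "response": _RESPONSE_DEFAULTS,
        "signatures": _SIGNATURE_DEFAULTS,
    },
}

_REQUIRED_KEYS = [
    ("seed",),
    ("study", "daylight_start_hour"),
    ("study", "daylight_end_hour"),
    ("study", "post_tag_exclusion_days"),
    ("study", "training_fraction"),
    ("study", "label_window_s"),
    ("study", "cv_folds"),
    ("study", "smooth_basis_k"),
    ("study", "min_bursts_per_hour"),
    ("study", "min_hours_per_day"),
    ("study", "scenario_deltas"),
    ("simulation", "n_birds"),
    ("simulation", "environment"),
    ("simulation", "response"),
    ("simulation", "signatures"),
]


def deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Return ``base`` recursively updated with ``override`` (non-mutating)."""
    merged = copy.deepcopy(dict(base))
    for key, value in override.items():
        if key in merged and isinstance(merged[key], Mapping) and isinstance(value, Mapping):
            merged[key] = deep_merge(merged[key], value)
        else:
            merged[key] = copy.deepcopy(value)
    return merged


def validate_config(cfg: Mapping[str, Any]) -> None:
    """Check required keys and structural invariants; raise ConfigError."""
    for path in _REQUIRED_KEYS:
        node: Any = cfg
        for part in path:
            if not isinstance(node, Mapping) or part not in node:
                raise ConfigError(f"missing required config key: {'.'.join(path)}")
            node = node[part]
    study = cfg["study"]
    span = study["daylight_end_hour"] - study["daylight_start_hour"]
    if span != 16:
        raise ConfigError(
            f"daylight window must span 16 hours, got {span} "
            f"([{study['daylight_start_hour']}, {study['daylight_end_hour']}))"
        )
    for key in ("post_tag_exclusion_days", "cv_folds", "smooth_basis_k",
                "min_bursts_per_hour", "min_hours_per_day", "label_window_s"):
        if study[key] <= 0:
            raise ConfigError(f"study.{key} must be positive, got {study[key]}")
    if not 0 < study["training_fraction"] <= 1:
        raise ConfigError(
            f"study.training_fraction must be in (0, 1], got {study['training_fraction']}"
        )
    mixture = cfg["simulation"]["response"].get("nondisplay_mixture", {})
    total = sum(mixture.values())
    if mixture and abs(total - 1.0) > 1e-8:
        raise ConfigError(f"simulation.response.nondisplay_mixture must sum to 1, got {total}")


def load_config(path: str | None = None, *, use_defaults: bool = True) -> dict[str, Any]:
    """Load a YAML config file merged over the package defaults and validate."""
    cfg: dict[str, Any] = copy.deepcopy(DEFAULT_CONFIG) if use_defaults else {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = deep_merge(cfg, user) if use_defaults else user
    validate_config(cfg)
    return cfg


def save_config(cfg: Mapping[str, Any], path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Typed view of the study constants (the ``study`` config section)."""

    daylight_start_hour: int = 5
    daylight_end_hour: int = 21
    post_tag_exclusion_days: int = 2
    training_fraction: float = 0.10
    label_window_s: int = 7
    cv_folds: int = 10
    smooth_basis_k: int = 4
    min_bursts_per_hour: int = 2
    min_hours_per_day: int = 11
    scenario_deltas: tuple = (1, 2, 3, 4, 5, 6, 7)
    decision_threshold: float = 0.5
    seed: int = 20150401
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "PipelineConfig":
        study = cfg.get("study", {})
        known = {f for f in cls.__dataclass_fields__ if f != "extras"}
        kwargs = {k: v for k, v in study.items() if k in known}
        extras = {k: v for k, v in study.items() if k not in known}
        if "scenario_deltas" in kwargs:
            kwargs["scenario_deltas"] = tuple(kwargs["scenario_deltas"])
        return cls(seed=cfg.get("seed", 20150401), extras=extras, **kwargs)
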