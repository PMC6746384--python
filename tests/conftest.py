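import logging

import numpy as np
import pandas as pd
import pytest

from lekaccel.activity_aggregation import (build_burst_table, build_daily_table,
                                           hourly_proportions, qualify_days)
from lekaccel.config import DEFAULT_CONFIG, deep_merge
from lekaccel.synthetic_data import (default_environment, default_response,
                                     default_signatures, generate_dataset,
                                     generate_default_dataset,
                                     generate_schedules)
from lekaccel.thermal_response_models import fit_daily_model, fit_hourly_model

logging.getLogger("lekaccel").setLevel(logging.ERROR)

STUDY_SEED = 101


@pytest.fixture(scope="session")
def default_study():
    """One full default synthetic study, shared across the suite."""
    return generate_default_dataset(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def small_study():
    """A fast 4-bird study for unit tests."""
    schedules = generate_schedules(4, seed=7, start_day_min=100, start_day_max=120)
    return generate_dataset(schedules, default_environment(), default_response(),
                            default_signatures(), seed=7, missing_prob=0.05)


def true_label_frame(ds) -> pd.DataFrame:
    labels = ds.bursts.copy()
    labels["display"] = (labels["true_class"] == "display").astype(int)
    return labels


@pytest.fixture(scope="session")
def study_tables(default_study):
    """Burst-level and daily modelling tables built from true labels."""
    ds = default_study
    labels = true_label_frame(ds)
    bt = build_burst_table(labels, ds.schedules)
    hourly = hourly_proportions(bt)
    qualified = qualify_days(hourly)
    site_of = {s.bird_id: s.site_id for s in ds.schedules}
    dt = build_daily_table(hourly, qualified, ds.temperatures, site_of)
    return bt, dt


@pytest.fixture(scope="session")
def hourly_fit(study_tables):
    bt, _ = study_tables
    return fit_hourly_model(bt)


@pytest.fixture(scope="session")
def daily_fit(study_tables):
    _, dt = study_tables
    return fit_daily_model(dt)


def make_null_dataset(seed: int, n_birds: int = 6, intercept: float = -0.3,
                      bird_sd: float = 0.0, missing_prob: float = 0.0):
    """Dataset whose true response has no covariate effects."""
    cfg = deep_merge(DEFAULT_CONFIG, {"simulation": {"response": {
        "intercept": intercept,
        "temp_values": [0.0] * 5,
        "hour_values": [0.0] * 6,
        "date_values": [0.0] * 4,
        "bird_sd": bird_sd,
    }}})
    schedules = generate_schedules(n_birds, seed=seed)
    return generate_dataset(schedules, default_environment(cfg),
                            default_response(cfg), default_signatures(cfg),
                            seed=seed, missing_prob=missing_prob)
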