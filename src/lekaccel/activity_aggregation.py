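"""Temporal filters and construction of the two modelling tables.

Burst-level: daylight window [5, 21), first two tracking days excluded.
Day-level: a bird-day enters the daily table only if at least
``min_bursts_per_hour`` bursts exist in at least ``min_hours_per_day`` of
the 16 daylight hours; its display activity is the unweighted mean of
hourly display proportions (hours with >= 1 burst), its temperature the
mean of the site's 16 daylight hourly readings.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .accel_io import get_logger, log_filter
from .synthetic_data import BirdSchedule

__all__ = [
    "apply_study_window",
    "build_burst_table",
    "build_daily_table",
    "hourly_proportions",
    "predictor_correlations",
    "qualify_days",
]


def apply_study_window(bursts: pd.DataFrame, schedules: Sequence[BirdSchedule],
                       *, daylight: tuple[int, int] = (5, 21),
                       post_tag_days: int = 2) -> pd.DataFrame:
    """Drop bursts in the first ``post_tag_days`` days after tagging and
    outside the half-open daylight window [start, end)."""
    start_map = {s.bird_id: s.start_day for s in schedules}
    unknown = set(bursts["bird_id"].unique()) - set(start_map)
    if unknown:
        raise ValueError(f"bursts for bird(s) with no schedule: {sorted(unknown)}")

    n0 = len(bursts)
    first_ok = bursts["bird_id"].map(start_map) + post_tag_days
    kept = bursts[bursts["jdate"] >= first_ok]
    log_filter("aggregate", "post_tag_exclusion", n0, len(kept))

    n1 = len(kept)
    lo, hi = daylight
    kept = kept[(kept["hour"] >= lo) & (kept["hour"] < hi)]
    log_filter("aggregate", "daylight_window", n1, len(kept))
    return kept.reset_index(drop=True)


def build_burst_table(labels: pd.DataFrame, schedules: Sequence[BirdSchedule],
                      *, daylight: tuple[int, int] = (5, 21),
                      post_tag_days: int = 2) -> pd.DataFrame:
    """Burst-level modelling table: bird_id, jdate, hour, hour_frac,
    temp_c, display (0/1), after the study-window filters; bursts with no
    temperature assignment are excluded (logged)."""
    df = apply_study_window(labels, schedules, daylight=daylight,
                            post_tag_days=post_tag_days)
    n0 = len(df)
    df = df[df["temp_c"].notna()]
    log_filter("aggregate", "missing_temperature", n0, len(df))
    out = df[["bird_id", "site_id", "jdate", "hour", "temp_c", "display"]].copy()
    out["hour_frac"] = df["hour"] + df.get("minute", 0) / 60.0
    return out.reset_index(drop=True)


def hourly_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Per (bird, day, hour): burst count and display proportion.

    Cells with no bursts are absent, not zero.
    """
    grouped = (records.groupby(["bird_id", "jdate", "hour"], as_index=False)
               .agg(n_bursts=("display", "size"), n_display=("display", "sum")))
    grouped["proportion"] = grouped["n_display"] / grouped["n_bursts"]
    return grouped


def qualify_days(hourly: pd.DataFrame, *, min_bursts_per_hour: int = 2,
                 min_hours_per_day: int = 11) -> set[tuple[str, int]]:
    """Bird-days with >= min_bursts_per_hour bursts in >=
    min_hours_per_day distinct daylight hours."""
    good_hours = hourly[hourly["n_bursts"] >= min_bursts_per_hour]
    counts = good_hours.groupby(["bird_id", "jdate"])["hour"].nunique()
    qualified = counts[counts >= min_hours_per_day]
    log_filter("aggregate", "day_qualification",
               hourly.groupby(["bird_id", "jdate"]).ngroups, len(qualified))
    return {(b, int(d)) for b, d in qualified.index}


def build_daily_table(hourly: pd.DataFrame, qualified: Iterable[tuple[str, int]],
                      temps: pd.DataFrame, site_of_bird: Mapping[str, str],
                      *, daylight: tuple[int, int] = (5, 21),
                      max_missing_temp_hours: int = 2) -> pd.DataFrame:
    """Daily modelling table for qualified bird-days.

    display_activity is the unweighted mean of the day's hourly proportions
    (all daylight hours with >= 1 burst); daytime_mean_temp averages the
    site's hourly readings over the full daylight window regardless of
    burst coverage.  Days whose temperature series misses more than
    ``max_missing_temp_hours`` daylight readings raise.
    """
    qualified = set(qualified)
    if not qualified:
        raise ValueError("no qualified bird-days")
    lo, hi = daylight
    day_temps = temps[(temps["hour"] >= lo) & (temps["hour"] < hi)]
    temp_mean = day_temps.groupby(["site_id", "jdate"])["temp_c"].agg(["mean", "size"])

    rows = []
    for (bird, day), grp in hourly.groupby(["bird_id", "jdate"]):
        if (bird, int(day)) not in qualified:
            continue
        site = site_of_bird[bird]
        try:
            tstat = temp_mean.loc[(site, int(day))]
        except KeyError:
            raise ValueError(f"no temperature data for site {site} day {day}")
        n_expected = hi - lo
        if tstat["size"] < n_expected - max_missing_temp_hours:
            raise ValueError(
                f"site {site} day {day}: only {int(tstat['size'])}/{n_expected} "
                f"daylight temperature readings (tolerance {max_missing_temp_hours})")
        rows.append({
            "bird_id": bird,
            "jdate": int(day),
            "display_activity": float(grp["proportion"].mean()),
            "daytime_mean_temp": float(tstat["mean"]),
            "n_hours_used": int(len(grp)),
        })
    out = pd.DataFrame(rows).sort_values(["bird_id", "jdate"]).reset_index(drop=True)
    get_logger("aggregate").info("daily table: %d bird-days", len(out))
    return out


def predictor_correlations(burst_table: pd.DataFrame,
                           daily_table: pd.DataFrame | None = None) -> dict[str, float]:
    """Multi-collinearity diagnostics, logged at table-build time."""
    out = {
        "temp_vs_hour": float(np.corrcoef(burst_table["temp_c"],
                                          burst_table["hour_frac"])[0, 1]),
        "temp_vs_jdate": float(np.corrcoef(burst_table["temp_c"],
                                           burst_table["jdate"])[0, 1]),
        "hour_vs_jdate": float(np.corrcoef(burst_table["hour_frac"],
                                           burst_table["jdate"])[0, 1]),
    }
    if daily_table is not None and len(daily_table) > 2:
        out["daily_temp_vs_jdate"] = float(np.corrcoef(
            daily_table["daytime_mean_temp"], daily_table["jdate"])[0, 1])
    get_logger("aggregate").info(
        "predictor correlations: %s",
        ", ".join(f"{k}={v:.3f}" for k, v in out.items()))
    return out
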