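"""File formats, validation and structured logging for the pipeline.

Canonical on-disk formats (all plain CSV/JSON so datasets survive text-only
transport):

* bursts CSV — long format, one row per 1-Hz sample:
  ``bird_id, site_id, timestamp, sample_index, sway_g, surge_g, heave_g``
* labels CSV — one row per burst: ``bird_id, timestamp, label``
* temperature CSV — one row per site-hour: ``site_id, timestamp, temp_c``
* truth JSON — the generator's tabulated response surface.

Parsing failures carry file and line context; malformed bursts are rejected
individually (named error per burst) while the rest of the file loads.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig  # noqa: F401  (re-export per module contract)
from .synthetic_data import SENSOR_RANGE_G, SyntheticDataset

__all__ = [
    "AccelBurst",
    "BurstReadResult",
    "FormatError",
    "ParseIssue",
    "TemperatureSeries",
    "align_temperature",
    "bursts_to_frame",
    "get_logger",
    "log_filter",
    "read_bursts",
    "read_labels",
    "read_temperature",
    "read_truth",
    "write_bursts",
    "write_dataset",
    "write_labels",
    "write_temperature",
]

logger = logging.getLogger("lekaccel")

_BURST_COLUMNS = ["bird_id", "site_id", "timestamp", "sample_index",
                  "sway_g", "surge_g", "heave_g"]
MIN_SAMPLES = 7  # first 7 s needed for features


class FormatError(ValueError):
    """Raised on malformed input files in strict mode."""


def get_logger(stage: str) -> logging.Logger:
    return logger.getChild(stage)


def log_filter(stage: str, rule: str, n_in: int, n_out: int) -> None:
    """One structured log line per filter: stage, rule, counts in/out."""
    get_logger(stage).info("filter=%s in=%d out=%d removed=%d",
                           rule, n_in, n_out, n_in - n_out)


@dataclass(frozen=True)
class AccelBurst:
    """One accelerometer burst: >=7 samples of (sway, surge, heave) in g."""

    bird_id: str
    site_id: str
    timestamp: pd.Timestamp
    samples: np.ndarray  # (n_samples, 3)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 3:
            raise ValueError(f"samples must be (n, 3), got shape {s.shape}")
        if s.shape[0] < MIN_SAMPLES:
            raise ValueError(
                f"burst needs >= {MIN_SAMPLES} samples, got {s.shape[0]}")
        if np.any(np.abs(s) > SENSOR_RANGE_G + 1e-9):
            raise ValueError(f"acceleration outside +-{SENSOR_RANGE_G} g sensor range")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "timestamp", pd.Timestamp(self.timestamp))

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def __eq__(self, other) -> bool:
        return (isinstance(other, AccelBurst)
                and self.bird_id == other.bird_id
                and self.site_id == other.site_id
                and self.timestamp == other.timestamp
                and np.array_equal(self.samples, other.samples))


@dataclass(frozen=True)
class ParseIssue:
    """A named parse failure with file and line context."""

    error: str
    path: str
    line: int          # 1-based line number in the file (header = line 1)
    detail: str = ""

    def __str__(self) -> str:
        return f"{self.error} at {self.path}:{self.line} {self.detail}".rstrip()


@dataclass
class BurstReadResult:
    bursts: list[AccelBurst]
    issues: list[ParseIssue] = field(default_factory=list)

    def raise_if_issues(self) -> None:
        if self.issues:
            raise FormatError("; ".join(str(i) for i in self.issues[:5])
                              + (f" (+{len(self.issues) - 5} more)" if len(self.issues) > 5 else ""))


@dataclass
class TemperatureSeries:
    """Hourly temperatures for one site; timestamps strictly increasing."""

    site_id: str
    timestamps: pd.DatetimeIndex
    temp_c: np.ndarray

    def __post_init__(self) -> None:
        ts = pd.DatetimeIndex(self.timestamps)
        if len(ts) and not ts.is_monotonic_increasing:
            raise ValueError(f"site {self.site_id}: timestamps must be increasing")
        if len(ts) != len(np.unique(ts.asi8)):
            raise ValueError(f"site {self.site_id}: duplicate timestamps")
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "temp_c", np.asarray(self.temp_c, dtype=float))

    def gaps(self) -> pd.DatetimeIndex:
        """Missing hours between first and last reading (flagged, not filled)."""
        if len(self.timestamps) < 2:
            return pd.DatetimeIndex([])
        full = pd.date_range(self.timestamps[0], self.timestamps[-1], freq="h")
        return full.difference(self.timestamps)


# ---------------------------------------------------------------------------
# bursts
# ---------------------------------------------------------------------------

def bursts_to_frame(bursts: Iterable[AccelBurst]) -> pd.DataFrame:
    """Long-format frame of a burst collection (one row per sample)."""
    rows = []
    for b in bursts:
        n = b.n_samples
        rows.append(pd.DataFrame({
            "bird_id": b.bird_id,
            "site_id": b.site_id,
            "timestamp": b.timestamp.isoformat(),
            "sample_index": np.arange(n),
            "sway_g": b.samples[:, 0],
            "surge_g": b.samples[:, 1],
            "heave_g": b.samples[:, 2],
        }))
    if not rows:
        return pd.DataFrame(columns=_BURST_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def write_bursts(bursts, path: str | Path) -> None:
    """Write bursts (list of AccelBurst or a SyntheticDataset) to long CSV."""
    if isinstance(bursts, SyntheticDataset):
        ds = bursts
        n, k, _ = ds.samples.shape
        frame = pd.DataFrame({
            "bird_id": np.repeat(ds.bursts["bird_id"].to_numpy(), k),
            "site_id": np.repeat(ds.bursts["site_id"].to_numpy(), k),
            "timestamp": np.repeat(
                ds.bursts["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S").to_numpy(), k),
            "sample_index": np.tile(np.arange(k), n),
            "sway_g": ds.samples[:, :, 0].ravel(),
            "surge_g": ds.samples[:, :, 1].ravel(),
            "heave_g": ds.samples[:, :, 2].ravel(),
        })
    else:
        frame = bursts_to_frame(bursts)
    # %.17g round-trips float64 exactly (readers recover identical bursts)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_bursts(path: str | Path, *, strict: bool = False,
                out_of_range: str = "reject") -> BurstReadResult:
    """Read a long-format bursts CSV.

    Rows are grouped by (bird_id, timestamp) with samples ordered by
    sample_index.  Bursts with too few samples, non-contiguous sample
    indices, or (policy ``reject``) out-of-range accelerations are dropped
    with a :class:`ParseIssue` carrying the first offending line number;
    with ``out_of_range="clip"`` values are clipped to the sensor range
    with a warning instead.
    """
    if out_of_range not in ("reject", "clip"):
        raise ValueError("out_of_range must be 'reject' or 'clip'")
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _BURST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1

    bursts: list[AccelBurst] = []
    issues: list[ParseIssue] = []
    for (bird, ts), grp in df.groupby(["bird_id", "timestamp"], sort=True):
        grp = grp.sort_values("sample_index")
        line = int(grp["_line"].iloc[0])
        idx = grp["sample_index"].to_numpy()
        if len(idx) < MIN_SAMPLES:
            issues.append(ParseIssue("TooFewSamples", str(path), line,
                                     f"burst ({bird}, {ts}) has {len(idx)} samples"))
            continue
        if not np.array_equal(idx, np.arange(len(idx))):
            issues.append(ParseIssue("BadSampleIndex", str(path), line,
                                     f"burst ({bird}, {ts}) sample_index not 0..n-1"))
            continue
        samples = grp[["sway_g", "surge_g", "heave_g"]].to_numpy(dtype=float)
        if np.any(np.abs(samples) > SENSOR_RANGE_G):
            if out_of_range == "reject":
                issues.append(ParseIssue("OutOfRange", str(path), line,
                                         f"burst ({bird}, {ts}) exceeds +-{SENSOR_RANGE_G} g"))
                continue
            get_logger("io").warning("clipping out-of-range burst (%s, %s)", bird, ts)
            samples = np.clip(samples, -SENSOR_RANGE_G, SENSOR_RANGE_G)
        site = str(grp["site_id"].iloc[0])
        bursts.append(AccelBurst(bird_id=str(bird), site_id=site,
                                 timestamp=pd.Timestamp(ts), samples=samples))
    result = BurstReadResult(bursts=bursts, issues=issues)
    if strict:
        result.raise_if_issues()
    for issue in issues:
        get_logger("io").warning("%s", issue)
    return result


# ---------------------------------------------------------------------------
# labels / temperature / truth
# ---------------------------------------------------------------------------

def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    out = labels.copy()
    if "timestamp" in out.columns and not pd.api.types.is_string_dtype(out["timestamp"]):
        out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def write_temperature(temps: pd.DataFrame, path: str | Path, year: int = 2015) -> None:
    """Write temperature table (site_id, jdate, hour, temp_c) as site/timestamp CSV."""
    out = temps.copy()
    if "timestamp" not in out.columns:
        base = pd.Timestamp(year=year, month=1, day=1)
        out["timestamp"] = (base + pd.to_timedelta(out["jdate"] - 1, unit="D")
                            + pd.to_timedelta(out["hour"], unit="h"))
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out[["site_id", "timestamp", "temp_c"]].to_csv(path, index=False)


def read_temperature(path: str | Path) -> pd.DataFrame:
    """Read temperature CSV to (site_id, timestamp, jdate, hour, temp_c)."""
    df = pd.read_csv(path)
    for col in ("site_id", "timestamp", "temp_c"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["jdate"] = df["timestamp"].dt.dayofyear
    df["hour"] = df["timestamp"].dt.hour
    for site, grp in df.groupby("site_id"):
        series = TemperatureSeries(str(site), pd.DatetimeIndex(grp["timestamp"]),
                                   grp["temp_c"].to_numpy())
        gaps = series.gaps()
        if len(gaps):
            get_logger("io").warning("site %s temperature series has %d missing hours",
                                     site, len(gaps))
    return df


def align_temperature(bursts: pd.DataFrame | Sequence[AccelBurst],
                      temps: pd.DataFrame) -> pd.Series:
    """Assign each burst its site's temperature for the clock hour of the
    burst START (no interpolation).

    Accepts a burst table (columns bird_id, site_id, and either
    jdate+hour or timestamp) or a list of AccelBurst.  Returns a float
    Series aligned to the input order; missing hours are NaN (flagged by a
    warning, excluded downstream — never silently interpolated).
    """
    if not isinstance(bursts, pd.DataFrame):
        bursts = pd.DataFrame({
            "bird_id": [b.bird_id for b in bursts],
            "site_id": [b.site_id for b in bursts],
            "timestamp": [b.timestamp for b in bursts],
        })
    df = bursts.copy()
    if "jdate" not in df.columns or "hour" not in df.columns:
        ts = pd.to_datetime(df["timestamp"])
        df["jdate"] = ts.dt.dayofyear
        df["hour"] = ts.dt.hour
    known_sites = set(temps["site_id"].unique())
    missing_sites = set(df["site_id"].unique()) - known_sites
    if missing_sites:
        raise FormatError(f"no temperature series for site(s): {sorted(missing_sites)}")
    lookup = temps.drop_duplicates(["site_id", "jdate", "hour"])[
        ["site_id", "jdate", "hour", "temp_c"]]
    merged = df.merge(lookup, on=["site_id", "jdate", "hour"], how="left",
                      suffixes=("", "_assigned"))
    col = "temp_c_assigned" if "temp_c_assigned" in merged.columns else "temp_c"
    out = merged[col]
    n_missing = int(out.isna().sum())
    if n_missing:
        get_logger("io").warning("%d bursts at hours with no temperature reading "
                                 "(flagged NaN, excluded downstream)", n_missing)
    out.index = bursts.index
    return out.rename("temp_c")


# ---------------------------------------------------------------------------
# dataset bundle
# ---------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic study (bursts, labels, temperature, truth, schedules)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bursts": out / "bursts.csv",
        "labels": out / "labels.csv",
        "temperature": out / "temperature.csv",
        "truth": out / "truth.json",
        "schedules": out / "schedules.csv",
    }
    write_bursts(ds, paths["bursts"])
    write_labels(ds.labels.assign(label=ds.bursts["true_class"])
                 [["bird_id", "timestamp", "label"]], paths["labels"])
    write_temperature(ds.temperatures, paths["temperature"],
                      year=int(ds.bursts["timestamp"].dt.year.iloc[0]) if len(ds.bursts) else 2015)
    with open(paths["truth"], "w") as fh:
        json.dump(ds.truth, fh, indent=1)
    pd.DataFrame([vars(s) for s in ds.schedules]).to_csv(paths["schedules"], index=False)
    return paths


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
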