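"""Per-burst summary-statistic features for the behaviour classifiers.

All statistics are computed on the first ``window_s`` samples (default 7 s
at 1 Hz) of each axis.  Conventions, fixed across the pipeline:

* sd and covariance use the n-1 denominator;
* skewness is the (biased) third standardized moment m3 / m2^1.5 and
  kurtosis is excess kurtosis m4 / m2^2 - 3;
* quantiles interpolate linearly between order statistics;
* zero-variance axes yield skewness = kurtosis = 0 and Pearson r = 0;
* "vector norm" features summarize the per-sample Euclidean norm of the
  (sway, surge, heave) vector by its mean and sd;
* the pairwise "mean absolute difference" is mean(|a_i - b_i|) on raw
  samples;
* ODBA removes the per-axis within-window mean (static component) and
  averages |d_sway| + |d_surge| + |d_heave| over samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AXES

__all__ = ["FEATURE_NAMES", "DEFAULT_WINDOW_S", "extract_features",
           "feature_table", "odba"]

DEFAULT_WINDOW_S = 7

_AXIS_STATS = ("mean", "sd", "skew", "kurt", "min", "max", "q25", "q50", "q75")
_PAIRS = ((0, 1), (0, 2), (1, 2))  # (sway,surge), (sway,heave), (surge,heave)
_PAIR_STATS = ("cov", "corr", "mad")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"{ax}_{st}" for ax in AXES for st in _AXIS_STATS]
    + [f"{AXES[i]}_{AXES[j]}_{st}" for i, j in _PAIRS for st in _PAIR_STATS]
    + ["norm_mean", "norm_sd", "odba"]
)


def _as_batch(samples) -> np.ndarray:
    s = np.asarray(samples, dtype=float)
    if s.ndim == 2:
        s = s[None, :, :]
    if s.ndim != 3 or s.shape[2] != 3:
        raise ValueError(f"samples must be (n_bursts, n_samples, 3), got {s.shape}")
    return s


def _feature_matrix(x: np.ndarray, window_s: int) -> np.ndarray:
    """(n_bursts, n_features) matrix; x is (n_bursts, n_samples, 3)."""
    if window_s < 1:
        raise ValueError(f"window_s must be >= 1, got {window_s}")
    if x.shape[1] < window_s:
        raise ValueError(
            f"bursts have {x.shape[1]} samples; need >= window_s={window_s}")
    w = x[:, :window_s, :]                      # (n, w, 3)
    nw = w.shape[1]

    mean = w.mean(axis=1)                       # (n, 3)
    d = w - mean[:, None, :]
    m2 = (d ** 2).mean(axis=1)
    m3 = (d ** 3).mean(axis=1)
    m4 = (d ** 4).mean(axis=1)
    sd = np.sqrt((d ** 2).sum(axis=1) / (nw - 1)) if nw > 1 else np.zeros_like(mean)
    nonzero = m2 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(nonzero, m3 / np.where(nonzero, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(nonzero, m4 / np.where(nonzero, m2, 1.0) ** 2 - 3.0, 0.0)
    qs = np.quantile(w, [0.25, 0.50, 0.75], axis=1)  # (3, n, 3)

    cols = []
    for a in range(3):
        cols.extend([mean[:, a], sd[:, a], skew[:, a], kurt[:, a],
                     w[:, :, a].min(axis=1), w[:, :, a].max(axis=1),
                     qs[0, :, a], qs[1, :, a], qs[2, :, a]])

    for i, j in _PAIRS:
        cross = (d[:, :, i] * d[:, :, j]).sum(axis=1)
        cov = cross / (nw - 1) if nw > 1 else np.zeros(len(w))
        denom = np.sqrt((d[:, :, i] ** 2).sum(axis=1) * (d[:, :, j] ** 2).sum(axis=1))
        ok = denom > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(ok, cross / np.where(ok, denom, 1.0), 0.0)
        mad = np.abs(w[:, :, i] - w[:, :, j]).mean(axis=1)
        cols.extend([cov, corr, mad])

    norm = np.linalg.norm(w, axis=2)            # (n, w)
    norm_mean = norm.mean(axis=1)
    dn = norm - norm_mean[:, None]
    norm_sd = np.sqrt((dn ** 2).sum(axis=1) / (nw - 1)) if nw > 1 else np.zeros(len(w))
    odba_val = np.abs(d).sum(axis=2).mean(axis=1)
    cols.extend([norm_mean, norm_sd, odba_val])

    return np.column_stack(cols)


def extract_features(burst, window_s: int = DEFAULT_WINDOW_S) -> pd.Series:
    """Feature vector of one burst (AccelBurst or (n_samples, 3) array)."""
    samples = getattr(burst, "samples", burst)
    mat = _feature_matrix(_as_batch(samples), window_s)
    return pd.Series(mat[0], index=list(FEATURE_NAMES), name="features")


def odba(burst, window_s: int = DEFAULT_WINDOW_S) -> float:
    """Overall dynamic body acceleration of one burst (g).

    Static component per axis is the within-window mean; ODBA is the mean
    over samples of |d_sway| + |d_surge| + |d_heave|.
    """
    samples = np.asarray(getattr(burst, "samples", burst), dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError(f"burst samples must be (n, 3), got {samples.shape}")
    if samples.shape[0] < window_s:
        raise ValueError(f"burst has {samples.shape[0]} samples; need >= {window_s}")
    w = samples[:window_s]
    d = w - w.mean(axis=0)
    return float(np.abs(d).sum(axis=1).mean())


def feature_table(bursts, window_s: int = DEFAULT_WINDOW_S,
                  keys: pd.DataFrame | None = None) -> pd.DataFrame:
    """Feature table for many bursts.

    ``bursts`` may be an (n_bursts, n_samples, 3) array, a list of
    AccelBurst, or a SyntheticDataset.  Optional ``keys`` columns (e.g.
    burst_id, bird_id, timestamp) are prepended to the feature columns.
    """
    from .synthetic_data import SyntheticDataset

    if isinstance(bursts, SyntheticDataset):
        keys = bursts.bursts[["burst_id", "bird_id", "site_id", "timestamp"]] if keys is None else keys
        arr = bursts.samples
    elif isinstance(bursts, np.ndarray):
        arr = bursts
    else:
        bursts = list(bursts)
        lengths = {b.n_samples for b in bursts}
        if len(lengths) > 1:
            arr = np.stack([b.samples[:min(lengths)] for b in bursts])
        else:
            arr = np.stack([b.samples for b in bursts]) if bursts else np.empty((0, window_s, 3))
        if keys is None and bursts:
            keys = pd.DataFrame({
                "bird_id": [b.bird_id for b in bursts],
                "site_id": [b.site_id for b in bursts],
                "timestamp": [b.timestamp for b in bursts],
            })
    mat = _feature_matrix(_as_batch(arr), window_s) if len(arr) else np.empty((0, len(FEATURE_NAMES)))
    feats = pd.DataFrame(mat, columns=list(FEATURE_NAMES))
    if keys is not None:
        feats = pd.concat([keys.reset_index(drop=True), feats], axis=1)
    return feats
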