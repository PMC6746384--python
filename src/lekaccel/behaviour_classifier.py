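"""Supervised display/non-display classification of accelerometer bursts.

A small labeled subset (default 10% of bursts) trains several candidate
model families; families are compared by k-fold cross-validated precision
and recall for the display class (pooled over fold confusion matrices), the
best is refit on the full labeled subset and used to label the remainder.

Labels are binary throughout — display vs everything else — even though the
synthetic generator knows five classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GroupKFold, KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .accel_io import get_logger
from .burst_features import DEFAULT_WINDOW_S, FEATURE_NAMES, feature_table
from .synthetic_data import SyntheticDataset, substream

__all__ = [
    "CVReport",
    "FAMILY_ORDER",
    "LabeledSet",
    "classify_remaining",
    "classify_study",
    "fit_family",
    "make_training_subset",
    "select_best",
    "train_and_cv",
]

#: Fixed family order, also the tie-break order in select_best.
FAMILY_ORDER = ("random_forest", "decision_tree", "knn", "linear_svm")


def _make_model(family: str, seed: int, *, forest_size: int = 500,
                knn_neighbors: int = 5):
    if family == "random_forest":
        return RandomForestClassifier(n_estimators=forest_size, random_state=seed,
                                      n_jobs=1)
    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if family == "knn":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=knn_neighbors))
    if family == "linear_svm":
        return make_pipeline(StandardScaler(), LinearSVC(random_state=seed))
    raise ValueError(f"unknown model family {family!r}; known: {FAMILY_ORDER}")


@dataclass
class LabeledSet:
    """Feature vectors with binary display labels for a set of bursts."""

    features: pd.DataFrame          # columns = FEATURE_NAMES
    labels: np.ndarray              # bool, True = display
    burst_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=bool)
        self.burst_ids = np.asarray(self.burst_ids)
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.burst_ids):
            raise ValueError("features, labels and burst_ids must have equal length")
        if len(np.unique(self.burst_ids)) != len(self.burst_ids):
            raise ValueError("duplicate burst in labeled set")
        missing = [c for c in FEATURE_NAMES if c not in self.features.columns]
        if missing:
            raise ValueError(f"labeled set missing feature columns: {missing[:3]}...")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def X(self) -> np.ndarray:
        return self.features[list(FEATURE_NAMES)].to_numpy()


@dataclass
class CVReport:
    """Cross-validation result for one model family.

    ``fold_confusions`` holds per-fold (tn, fp, fn, tp) counts; precision
    and recall for the display class are pooled over folds.
    """

    family: str
    fold_confusions: list[tuple[int, int, int, int]]
    seed: int
    skipped_folds: list[str] = field(default_factory=list)

    def _pooled(self) -> tuple[int, int, int, int]:
        arr = np.array(self.fold_confusions, dtype=int).reshape(-1, 4)
        tn, fp, fn, tp = arr.sum(axis=0)
        return int(tn), int(fp), int(fn), int(tp)

    @property
    def precision(self) -> float:
        tn, fp, fn, tp = self._pooled()
        return tp / (tp + fp) if tp + fp else 0.0

    @property
    def recall(self) -> float:
        tn, fp, fn, tp = self._pooled()
        return tp / (tp + fn) if tp + fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    @property
    def n(self) -> int:
        return sum(self._pooled())


def make_training_subset(dataset: SyntheticDataset, fraction: float = 0.10,
                         seed: int = 0, *, n: int | None = None,
                         window_s: int = DEFAULT_WINDOW_S) -> LabeledSet:
    """Uniform random sample (without replacement) of labeled bursts.

    Truth labels are collapsed to binary display / non-display.  ``n``
    overrides the fraction with an exact subset size.
    """
    total = len(dataset.bursts)
    if total == 0:
        raise ValueError("dataset is empty")
    if n is None:
        if not 0.0 < fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        n = int(round(fraction * total))
    if not 1 <= n <= total:
        raise ValueError(f"subset size {n} outside [1, {total}]")
    rng = substream(seed, "training_subset")
    idx = np.sort(rng.choice(total, size=n, replace=False))
    feats = feature_table(dataset.samples[idx], window_s=window_s)
    labels = (dataset.bursts["true_class"].to_numpy()[idx] == "display")
    return LabeledSet(features=feats, labels=labels,
                      burst_ids=dataset.bursts["burst_id"].to_numpy()[idx])


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(y_true & y_pred))
    tn = int(np.sum(~y_true & ~y_pred))
    fp = int(np.sum(~y_true & y_pred))
    fn = int(np.sum(y_true & ~y_pred))
    return tn, fp, fn, tp


def train_and_cv(labeled: LabeledSet, families: Sequence[str] = FAMILY_ORDER,
                 k: int = 10, seed: int = 0, *, groups: np.ndarray | None = None,
                 forest_size: int = 500, knn_neighbors: int = 5) -> list[CVReport]:
    """k-fold cross-validation of each family on the labeled set.

    Folds are uniform random over bursts (or grouped if ``groups`` is
    given); each fold is predicted by a model trained on the other k-1.
    A fold whose training part has a single class is reported and skipped
    for that family.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(labeled) < k:
        raise ValueError(f"labeled set of {len(labeled)} cannot form {k} folds")
    fold_seed = int(substream(seed, "cv_folds").integers(2**31 - 1))
    if groups is not None:
        splitter = GroupKFold(n_splits=k)
        splits = list(splitter.split(labeled.X, labeled.labels, groups))
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=fold_seed)
        splits = list(splitter.split(labeled.X))

    X, y = labeled.X, labeled.labels
    reports = []
    log = get_logger("classify")
    for family in families:
        confusions, skipped = [], []
        for i, (tr, te) in enumerate(splits):
            if len(np.unique(y[tr])) < 2:
                skipped.append(f"fold {i}: single-class training split")
                continue
            model = _make_model(family, fold_seed + i, forest_size=forest_size,
                                knn_neighbors=knn_neighbors)
            try:
                model.fit(X[tr], y[tr])
                pred = model.predict(X[te]).astype(bool)
            except Exception as exc:  # pragma: no cover - backend-specific
                skipped.append(f"fold {i}: {exc}")
                continue
            confusions.append(_confusion(y[te], pred))
        if not confusions:
            log.warning("family %s skipped entirely: %s", family, "; ".join(skipped))
            continue
        report = CVReport(family=family, fold_confusions=confusions,
                          seed=fold_seed, skipped_folds=skipped)
        log.info("family=%s precision=%.4f recall=%.4f", family,
                 report.precision, report.recall)
        reports.append(report)
    return reports


def select_best(reports: Sequence[CVReport]) -> str:
    """Family with the best display-class F1; ties broken by precision,
    then by the fixed FAMILY_ORDER."""
    if not reports:
        raise ValueError("no CV reports to select from")

    def order_rank(r: CVReport) -> int:
        return FAMILY_ORDER.index(r.family) if r.family in FAMILY_ORDER else len(FAMILY_ORDER)

    best = sorted(reports, key=lambda r: (-r.f1, -r.precision, order_rank(r)))[0]
    return best.family


def fit_family(labeled: LabeledSet, family: str, seed: int = 0, *,
               forest_size: int = 500, knn_neighbors: int = 5):
    """Refit a family on the full labeled subset (the deployment model)."""
    model = _make_model(family, int(substream(seed, "cv_folds").integers(2**31 - 1)),
                        forest_size=forest_size, knn_neighbors=knn_neighbors)
    model.fit(labeled.X, labeled.labels)
    return model


def classify_remaining(model, features: pd.DataFrame) -> np.ndarray:
    """Predict binary display labels for unlabeled bursts."""
    missing = [c for c in FEATURE_NAMES if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing: {missing[:3]}...")
    if len(features) == 0:
        return np.zeros(0, dtype=bool)
    return model.predict(features[list(FEATURE_NAMES)].to_numpy()).astype(bool)


def classify_study(dataset: SyntheticDataset, *, fraction: float = 0.10,
                   k: int = 10, seed: int = 0,
                   families: Sequence[str] = FAMILY_ORDER,
                   window_s: int = DEFAULT_WINDOW_S,
                   forest_size: int = 500, knn_neighbors: int = 5,
                   n_train: int | None = None) -> tuple[pd.DataFrame, list[CVReport], str]:
    """End-to-end labeling of a study.

    Draws the training subset, cross-validates all families, selects the
    best, refits it, and labels every burst: training bursts keep their
    given (true) labels, the remainder gets model predictions.  Returns the
    per-burst label table, the CV reports, and the selected family.
    """
    labeled = make_training_subset(dataset, fraction=fraction, seed=seed,
                                   n=n_train, window_s=window_s)
    reports = train_and_cv(labeled, families=families, k=k, seed=seed,
                           forest_size=forest_size, knn_neighbors=knn_neighbors)
    best = select_best(reports)
    model = fit_family(labeled, best, seed=seed, forest_size=forest_size,
                       knn_neighbors=knn_neighbors)

    all_ids = dataset.bursts["burst_id"].to_numpy()
    in_train = np.isin(all_ids, labeled.burst_ids)
    feats = feature_table(dataset.samples[~in_train], window_s=window_s)
    pred = classify_remaining(model, feats)

    # training bursts keep their given labels; remainder is predicted
    display = np.zeros(len(all_ids), dtype=bool)
    train_map = dict(zip(labeled.burst_ids, labeled.labels))
    display[in_train] = [train_map[b] for b in all_ids[in_train]]
    display[~in_train] = pred

    out = dataset.bursts[["burst_id", "bird_id", "site_id", "timestamp",
                          "jdate", "hour", "minute", "temp_c"]].copy()
    out["display"] = display.astype(int)
    out["in_training"] = in_train
    out["model_family"] = best
    return out, reports, best
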