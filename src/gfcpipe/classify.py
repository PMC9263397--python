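"""Leave-one-out SVM classification from regional GFC features.

Each subject is predicted by a support vector machine trained on all other
subjects (LOOCV); feature standardization is fitted on the training fold
only, so no information from the held-out subject leaks into the model.
Defaults follow LIBSVM conventions: RBF kernel, C = 1, gamma = 1/n_features;
a linear kernel and an unscaled mode are available.  Aggregated confusion
counts yield accuracy, sensitivity and specificity as exact fractions,
reported as percentages rounded to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.svm import SVC


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "auto"   # "auto" = 1/n_features, the LIBSVM default
    standardize: bool = True


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; positives are the clinical group of interest."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ClassificationError("confusion counts must be nonnegative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    sensitivity: float
    specificity: float


def classification_metrics(counts: ConfusionCounts) -> ClassificationMetrics:
    """Accuracy, sensitivity, specificity in percent (2-decimal rounding).

    Computed with exact rational arithmetic before rounding:
    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP).
    """
    total = counts.tp + counts.fn + counts.tn + counts.fp
    if total == 0 or counts.n_positive == 0 or counts.n_negative == 0:
        raise ClassificationError("metric denominators must be positive")

    def pct(num: int, den: int) -> float:
        return round(float(Fraction(100 * num, den)), 2)

    return ClassificationMetrics(
        accuracy=pct(counts.tp + counts.tn, total),
        sensitivity=pct(counts.tp, counts.n_positive),
        specificity=pct(counts.tn, counts.n_negative),
    )


def _check_features(x: np.ndarray, y: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ClassificationError("features must be finite (no missing values)")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ClassificationError("exactly two classes required")
    if counts.min() < 3:
        raise ClassificationError("each class needs at least 3 subjects")


def loocv_svm(
    features: pd.DataFrame,
    labels,
    positive_label,
    config: SVMConfig = SVMConfig(),
) -> tuple[ConfusionCounts, np.ndarray]:
    """Leave-one-out SVM classification.

    Parameters
    ----------
    features : DataFrame, subjects x feature columns (regional mean z-values)
    labels : per-subject class labels (two classes)
    positive_label : which class counts as positive for the confusion counts
    config : kernel/regularization/scaling settings

    Returns the aggregated confusion counts and the per-subject predicted
    labels, in the row order of `features`.
    """
    x = features.to_numpy(dtype=np.float64)
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ClassificationError("features and labels disagree on n subjects")
    _check_features(x, y)
    if positive_label not in y:
        raise ClassificationError(f"positive label {positive_label!r} not present")
    n = x.shape[0]
    preds = np.empty(n, dtype=y.dtype)
    for i in range(n):
        train = np.arange(n) != i
        x_tr, y_tr = x[train], y[train]
        if np.unique(y_tr).size < 2:
            raise ClassificationError("a training fold lost one class entirely")
        if config.standardize:
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0)
            sd[sd == 0] = 1.0
            x_tr = (x_tr - mu) / sd
            x_te = (x[i] - mu) / sd
        else:
            x_te = x[i]
        clf = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma)
        clf.fit(x_tr, y_tr)
        preds[i] = clf.predict(x_te[None, :])[0]
    pos = y == positive_label
    counts = ConfusionCounts(
        tp=int((pos & (preds == positive_label)).sum()),
        fn=int((pos & (preds != positive_label)).sum()),
        tn=int((~pos & (preds != positive_label)).sum()),
        fp=int((~pos & (preds == positive_label)).sum()),
    )
    return counts, preds


@dataclass(frozen=True)
class SubsetResult:
    features: tuple[str, ...]
    counts: ConfusionCounts
    metrics: ClassificationMetrics


def feature_subset_search(
    features: pd.DataFrame,
    labels,
    positive_label,
    max_subset_size: int | None = None,
    config: SVMConfig = SVMConfig(),
) -> list[SubsetResult]:
    """Exhaustive LOOCV over all nonempty feature subsets up to a size cap.

    Results are ranked by accuracy (descending), ties broken by fewer
    features, then by higher sensitivity.
    """
    cols = list(features.columns)
    if not cols:
        raise ClassificationError("at least one feature column required")
    if max_subset_size is None:
        max_subset_size = len(cols)
    max_subset_size = min(max_subset_size, len(cols))
    results = []
    for size in range(1, max_subset_size + 1):
        for subset in combinations(cols, size):
            counts, _ = loocv_svm(features[list(subset)], labels, positive_label, config)
            results.append(SubsetResult(subset, counts, classification_metrics(counts)))
    results.sort(key=lambda r: (-r.metrics.accuracy, len(r.features), -r.metrics.sensitivity))
    return results
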