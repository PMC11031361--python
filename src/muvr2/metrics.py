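"""Fitness measures and generic preprocessing for high-dimensional predictive models.

Regression fitness is measured by Q2 (cross-validated coefficient of
determination) or RMSEP; classification by the balanced error rate (BER), the
number of misclassifications (MISS), or the area under the ROC curve (AUROC,
binary targets only).  The module also provides one-hot encoding of categorical
variables and the conventional near-zero-variance filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "TargetVector",
    "FitnessValue",
    "METRIC_DIRECTIONS",
    "q2",
    "rmsep",
    "ber",
    "miss",
    "auroc",
    "fitness",
    "is_better",
    "one_hot_encode",
    "near_zero_variance_filter",
]

#: direction of optimization per metric
METRIC_DIRECTIONS = {
    "Q2": "maximize",
    "RMSEP": "minimize",
    "BER": "minimize",
    "MISS": "minimize",
    "AUROC": "maximize",
}

REGRESSION_METRICS = ("Q2", "RMSEP")
CLASSIFICATION_METRICS = ("BER", "MISS", "AUROC")


@dataclass(frozen=True)
class TargetVector:
    """The response variable: continuous values or categorical class labels."""

    values: np.ndarray
    kind: str  # "continuous" | "categorical"
    classes: tuple = ()

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 1 or len(values) < 2:
            raise ValueError("target must be one-dimensional with length >= 2")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.kind == "continuous":
            values = values.astype(float)
            if np.isnan(values).any():
                raise ValueError("missing values in target are not supported")
        else:
            if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in values):
                raise ValueError("missing values in target are not supported")
            classes = self.classes or tuple(np.unique(values).tolist())
            if len(classes) < 2:
                raise ValueError("categorical target needs >= 2 distinct classes")
            unseen = set(values.tolist()) - set(classes)
            if unseen:
                raise ValueError(f"target contains labels outside declared classes: {unseen}")
            object.__setattr__(self, "classes", tuple(classes))
        object.__setattr__(self, "values", values)

    @classmethod
    def from_values(cls, values: Sequence) -> "TargetVector":
        """Build a target, auto-detecting continuous vs categorical.

        String labels are categorical; numeric values are continuous except for
        exactly-two-valued vectors, which are treated as binary class labels.
        """
        arr = np.asarray(values)
        if arr.dtype.kind in "OUSb":
            return cls(arr, "categorical")
        if len(np.unique(arr)) == 2:
            return cls(arr, "categorical")
        return cls(arr.astype(float), "continuous")

    def __len__(self):
        return len(self.values)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def subset(self, idx) -> "TargetVector":
        return TargetVector(self.values[idx], self.kind, self.classes)


@dataclass(frozen=True)
class FitnessValue:
    metric: str
    value: float
    direction: str = field(default="")

    def __post_init__(self):
        if self.metric not in METRIC_DIRECTIONS:
            raise ValueError(f"unknown metric {self.metric!r}")
        object.__setattr__(self, "direction", METRIC_DIRECTIONS[self.metric])


def is_better(a: float, b: float, direction: str) -> bool:
    """True when fitness ``a`` is strictly better than ``b``."""
    return a > b if direction == "maximize" else a < b


def _as_float_pair(actual, predicted):
    a = np.asarray(actual, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if len(a) != len(p):
        raise ValueError(f"length mismatch: {len(a)} actual vs {len(p)} predicted")
    return a, p


def q2(actual, predicted, center=None) -> FitnessValue:
    """Cross-validated R2: 1 - SSres/SStot, with SStot around the mean of ``actual``.

    ``center`` overrides the reference mean (used when scoring a slice of
    pooled hold-out predictions against the full-target mean).
    """
    a, p = _as_float_pair(actual, predicted)
    mean = np.mean(a) if center is None else float(center)
    ss_tot = np.sum((a - mean) ** 2)
    if ss_tot <= 0:
        raise ValueError("degenerate target: zero variance in actual values")
    ss_res = np.sum((a - p) ** 2)
    return FitnessValue("Q2", 1.0 - ss_res / ss_tot)


def rmsep(actual, predicted) -> FitnessValue:
    """Root-mean-squared error of prediction."""
    a, p = _as_float_pair(actual, predicted)
    return FitnessValue("RMSEP", float(np.sqrt(np.mean((a - p) ** 2))))


def _check_classes(actual, predicted):
    a = np.asarray(actual)
    p = np.asarray(predicted)
    if len(a) != len(p):
        raise ValueError(f"length mismatch: {len(a)} actual vs {len(p)} predicted")
    extra = set(p.tolist()) - set(a.tolist())
    if extra:
        raise ValueError(f"predicted classes outside the actual class set: {extra}")
    return a, p


def ber(actual, predicted_classes) -> FitnessValue:
    """Balanced error rate: mean over (represented) classes of the per-class error rate."""
    a, p = _check_classes(actual, predicted_classes)
    rates = []
    for cls in np.unique(a):
        mask = a == cls
        rates.append(np.mean(p[mask] != cls))
    return FitnessValue("BER", float(np.mean(rates)))


def miss(actual, predicted_classes) -> FitnessValue:
    """Number of misclassifications."""
    a = np.asarray(actual)
    p = np.asarray(predicted_classes)
    if len(a) != len(p):
        raise ValueError(f"length mismatch: {len(a)} actual vs {len(p)} predicted")
    return FitnessValue("MISS", int(np.sum(a != p)))


def auroc(actual_binary, scores) -> FitnessValue:
    """Area under the ROC curve (rank-based; ties contribute 1/2). Binary targets only."""
    a = np.asarray(actual_binary)
    s = np.asarray(scores, dtype=float).ravel()
    classes = np.unique(a)
    if len(classes) != 2:
        raise ValueError("AUROC undefined: need exactly two classes, both present")
    if len(a) != len(s):
        raise ValueError("length mismatch between labels and scores")
    # positive class = second in sorted order, matching score orientation
    return FitnessValue("AUROC", float(roc_auc_score(a == classes[1], s)))


def fitness(metric: str, actual, predicted, center=None) -> FitnessValue:
    """Dispatch to the named fitness measure.

    ``predicted`` holds numbers for Q2/RMSEP, class labels for BER/MISS, and
    positive-class scores for AUROC.
    """
    metric = metric.upper()
    if metric == "Q2":
        return q2(actual, predicted, center=center)
    if metric == "RMSEP":
        return rmsep(actual, predicted)
    if metric == "BER":
        return ber(actual, predicted)
    if metric == "MISS":
        return miss(actual, predicted)
    if metric == "AUROC":
        return auroc(actual, predicted)
    raise ValueError(f"unknown metric {metric!r}")


def one_hot_encode(column: Sequence, levels: Sequence | None = None, name: str = "var"):
    """Full (no reference level dropped) one-hot encoding of a categorical column.

    Returns ``(matrix, column_names)`` where the matrix has one 0/1 column per
    level and every row sums to one.  Unseen levels raise.
    """
    col = np.asarray(column)
    if levels is None:
        levels = np.unique(col).tolist()
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError(f"categorical variable {name!r} has fewer than 2 levels")
    unseen = set(col.tolist()) - set(levels)
    if unseen:
        raise ValueError(f"unseen level(s) in {name!r}: {sorted(map(str, unseen))}")
    mat = np.zeros((len(col), len(levels)))
    for j, lev in enumerate(levels):
        mat[:, j] = col == lev
    names = [f"{name}_{lev}" for lev in levels]
    return mat, names


def near_zero_variance_filter(X, freq_ratio_cut: float = 19.0, unique_pct_cut: float = 10.0):
    """Indices of columns that survive the conventional near-zero-variance rule.

    A column is dropped when it is constant, or when the frequency ratio of its
    most common to second most common value exceeds ``freq_ratio_cut`` AND the
    percentage of unique values is below ``unique_pct_cut``.
    """
    X = np.asarray(X)
    if X.size == 0:
        raise ValueError("empty matrix")
    n = X.shape[0]
    kept = []
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        if len(counts) == 1:
            continue  # constant
        top = np.sort(counts)[::-1]
        freq_ratio = top[0] / top[1]
        unique_pct = 100.0 * len(counts) / n
        if freq_ratio > freq_ratio_cut and unique_pct < unique_pct_cut:
            continue
        kept.append(j)
    return np.asarray(kept, dtype=int)
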