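"""F-score feature ranking/selection and attribute scaling.

The F-score of feature *i* is the sum over classes of the squared deviation
of the class mean from the global mean, divided by the sum over classes of
the (n_c - 1 denominator) sample variances:

    F_i = sum_c (xbar_ic - xbar_i)^2  /  sum_c Var_c(feature i)

Higher scores mark features whose between-class spread dominates their
within-class noise; features below a user threshold (0.7 by default) are
dropped before classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import LabelMismatchError


@dataclass
class LabeledFeatureTable:
    """n specimens x p named features with class labels.

    ``X`` is a DataFrame (index = specimen ids, columns = feature names),
    ``y`` a Series of class labels aligned on the same index.
    """

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        self.X = pd.DataFrame(self.X)
        self.y = pd.Series(self.y)
        if len(self.X) != len(self.y):
            raise LabelMismatchError("X and y lengths differ")
        if not self.X.index.equals(self.y.index):
            self.y.index = self.X.index
        if self.X.shape[1] == 0:
            raise ValueError("feature table must have at least one feature")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list:
        return sorted(self.y.unique())

    def subset_rows(self, idx: np.ndarray) -> "LabeledFeatureTable":
        return LabeledFeatureTable(self.X.iloc[idx].copy(), self.y.iloc[idx].copy())

    def subset_columns(self, cols) -> "LabeledFeatureTable":
        return LabeledFeatureTable(self.X[list(cols)].copy(), self.y.copy())

    @classmethod
    def from_csv(cls, features_path: str | Path,
                 labels_path: str | Path) -> "LabeledFeatureTable":
        X = pd.read_csv(features_path, index_col=0)
        labels = pd.read_csv(labels_path, index_col=0)
        y = labels.iloc[:, 0]
        missing = X.index.difference(y.index)
        if len(missing):
            raise LabelMismatchError(f"specimens without labels: {list(missing)[:5]}")
        return cls(X, y.loc[X.index])


def f_scores(table: LabeledFeatureTable) -> pd.Series:
    """F-score of every feature, as a Series indexed by feature name.

    Classes with a single member are rejected (their sample variance is
    undefined); missing values are rejected. A zero denominator (every
    class constant in that feature) yields +inf with a warning.
    """
    sizes = table.y.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"every class needs >= 2 members for F-scores: {small}")
    if table.X.isna().any().any():
        raise ValueError("missing values in feature table")

    grand = table.X.mean(axis=0)
    grouped = table.X.groupby(table.y, sort=True)
    between = ((grouped.mean() - grand) ** 2).sum(axis=0)
    within = grouped.var(ddof=1).sum(axis=0)

    zero = within == 0
    if zero.any():
        warnings.warn(f"zero within-class variance for "
                      f"{within.index[zero].tolist()}; F-score set to inf",
                      stacklevel=2)
    with np.errstate(divide="ignore"):
        scores = between / within
    scores[zero & (between > 0)] = np.inf
    scores[zero & (between == 0)] = np.inf  # all-constant feature: also flagged
    return scores


def f_score(table: LabeledFeatureTable, i: int | str) -> float:
    """F-score of a single feature (by position or name)."""
    name = table.X.columns[i] if isinstance(i, (int, np.integer)) else i
    return float(f_scores(table)[name])


def select_features(table: LabeledFeatureTable,
                    threshold: float = 0.7) -> list[str]:
    """Names of features with F-score >= threshold, original order kept."""
    scores = f_scores(table)
    kept = [c for c in table.X.columns if scores[c] >= threshold]
    if not kept:
        warnings.warn("no feature reached the F-score threshold", stacklevel=2)
    return kept


@dataclass
class FeatureScaler:
    """Per-feature linear map fitted on a training table.

    Maps the train minimum to the lower bound and the train maximum to the
    upper bound ([0, 1] by default, [-1, 1] optional); values outside the
    training range map outside the bounds (no clipping). Constant features
    map to the lower bound.
    """

    feature_range: tuple[float, float] = (0.0, 1.0)
    mins_: pd.Series = field(default=None, repr=False)
    ranges_: pd.Series = field(default=None, repr=False)

    def fit(self, train: LabeledFeatureTable) -> "FeatureScaler":
        self.mins_ = train.X.min(axis=0)
        self.ranges_ = train.X.max(axis=0) - self.mins_
        constant = self.ranges_ == 0
        if constant.any():
            warnings.warn(f"constant features map to the lower bound: "
                          f"{self.ranges_.index[constant].tolist()}", stacklevel=2)
        return self

    def transform(self, table: LabeledFeatureTable) -> LabeledFeatureTable:
        lo, hi = self.feature_range
        ranges = self.ranges_.replace(0, np.inf)  # constant -> lower bound
        scaled = lo + (table.X - self.mins_) / ranges * (hi - lo)
        return LabeledFeatureTable(scaled, table.y.copy())


def scale_features(train: LabeledFeatureTable,
                   apply_to: LabeledFeatureTable | None = None,
                   feature_range: tuple[float, float] = (0.0, 1.0),
                   ) -> tuple[LabeledFeatureTable, LabeledFeatureTable | None]:
    """Fit min/max scaling on ``train`` only and apply it to both tables.

    Fitting exclusively on the training rows keeps the held-out test rows
    from leaking into the classifier's preprocessing.
    """
    scaler = FeatureScaler(feature_range=feature_range).fit(train)
    scaled_train = scaler.transform(train)
    scaled_apply = scaler.transform(apply_to) if apply_to is not None else None
    return scaled_train, scaled_apply
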