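"""Repeated random-subsampling cross-validation, confusion matrices and
the colors-vs-accuracy experiment.

The evaluation protocol: partition the n feature vectors uniformly at
random into 80% training and 20% test rows, fit scaling (and optionally
feature selection) on the training rows only, train the classifier,
predict the test rows; repeat (100 times by default) and pool all
predictions into a class x class confusion matrix. Back-end learners are
an RBF-kernel SVM and a random forest (mtry = 14, 500 trees by default).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .errors import LabelMismatchError
from .features import COLOR_FEATURE_NAMES, N_PALETTE
from .select import LabeledFeatureTable, scale_features, select_features

logger = logging.getLogger(__name__)


@dataclass
class CVConfig:
    """Configuration of the repeated-holdout evaluation."""

    n_reps: int = 100
    test_fraction: float = 0.2
    seed: int = 0
    classifier: str = "svm"           # "svm" or "rf"
    # SVM back-end
    svm_kernel: str = "rbf"
    svm_c: float = 10.0
    svm_gamma: float | str = "scale"
    grid_search: bool = False         # small LIBSVM-style (C, gamma) grid
    # RF back-end
    rf_mtry: int = 14
    rf_n_trees: int = 500
    # preprocessing per repetition
    scale_range: tuple[float, float] = (0.0, 1.0)
    selection_threshold: float | None = None   # per-repetition F-score cut

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.classifier not in {"svm", "rf"}:
            raise ValueError(f"unknown classifier {self.classifier!r}")


def train_classifier(train: LabeledFeatureTable, config: CVConfig,
                     seed: int | None = None):
    """Fit the configured back-end on a training table and return it."""
    if train.y.nunique() < 2:
        raise ValueError("training set holds a single class")
    seed = config.seed if seed is None else seed
    if config.classifier == "rf":
        model = RandomForestClassifier(
            n_estimators=config.rf_n_trees,
            max_features=min(config.rf_mtry, train.p),
            random_state=seed)
    elif config.grid_search:
        grid = {"C": [2.0 ** e for e in (-1, 1, 3, 5, 7)],
                "gamma": [2.0 ** e for e in (-7, -5, -3, -1, 1)]}
        model = GridSearchCV(SVC(kernel=config.svm_kernel), grid, cv=3)
    else:
        model = SVC(kernel=config.svm_kernel, C=config.svm_c,
                    gamma=config.svm_gamma, random_state=seed)
    model.fit(train.X.to_numpy(), train.y.to_numpy())
    return model


@dataclass
class CVResult:
    """Pooled predictions and per-repetition accuracies."""

    actual: list
    predicted: list
    accuracies: np.ndarray

    @property
    def n_predictions(self) -> int:
        return len(self.actual)

    @property
    def mean_accuracy(self) -> float:
        """Mean per-repetition accuracy, percent."""
        return float(np.mean(self.accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def repeated_holdout_cv(table: LabeledFeatureTable,
                        config: CVConfig) -> CVResult:
    """Repeated uniform 80/20 holdout evaluation.

    The partition is unstratified; a repetition whose training rows miss a
    class entirely is redrawn (and logged), since such a model could never
    predict that class. Scaling and optional F-score selection are fitted
    per repetition on the training rows only.
    """
    n = table.n
    if n < 10:
        raise ValueError("need at least 10 specimens for holdout CV")
    n_test = math.floor(config.test_fraction * n)
    n_classes = table.y.nunique()
    rng = np.random.default_rng(config.seed)

    actual: list = []
    predicted: list = []
    accuracies = np.empty(config.n_reps)
    for rep in range(config.n_reps):
        while True:
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if table.y.iloc[train_idx].nunique() == n_classes:
                break
            logger.info("repetition %d: redrawn (training set missed a class)",
                        rep)
        train = table.subset_rows(train_idx)
        test = table.subset_rows(test_idx)
        if config.selection_threshold is not None:
            kept = select_features(train, threshold=config.selection_threshold)
            if kept:
                train = train.subset_columns(kept)
                test = test.subset_columns(kept)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-feature notices per rep
            train, test = scale_features(train, test,
                                         feature_range=config.scale_range)
        model = train_classifier(train, config,
                                 seed=int(rng.integers(2 ** 31)))
        pred = model.predict(test.X.to_numpy())
        truth = test.y.to_numpy()
        actual.extend(truth.tolist())
        predicted.extend(pred.tolist())
        accuracies[rep] = 100.0 * float(np.mean(pred == truth))
    return CVResult(actual=actual, predicted=predicted, accuracies=accuracies)


@dataclass
class ConfusionMatrix:
    """Class x class prediction counts.

    ``counts`` has one row per predicted class and one column per actual
    class; entry (p, a) counts how often class a was predicted as p.
    Per-class accuracy is the diagonal count over the column sum, percent.
    """

    counts: pd.DataFrame

    @property
    def classes(self) -> list:
        return list(self.counts.columns)

    @property
    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def per_class_accuracy(self) -> pd.Series:
        diag = pd.Series(np.diag(self.counts), index=self.classes)
        return 100.0 * diag / self.column_sums

    @property
    def overall_accuracy(self) -> float:
        return 100.0 * float(np.trace(self.counts.to_numpy())) / self.total

    def to_frame(self) -> pd.DataFrame:
        """Report layout: counts plus Sum and Accuracy(%) rows."""
        out = self.counts.copy().astype(object)
        out.loc["Sum"] = self.column_sums
        out.loc["Accuracy(%)"] = self.per_class_accuracy.round(2)
        return out


def confusion_matrix(actual: list, predicted: list,
                     classes: list | None = None) -> ConfusionMatrix:
    """Tally (actual, predicted) pairs into a ConfusionMatrix."""
    if not actual:
        raise ValueError("no predictions to tally")
    if len(actual) != len(predicted):
        raise LabelMismatchError("actual and predicted lengths differ")
    if classes is None:
        classes = sorted(set(actual) | set(predicted))
    else:
        unknown = (set(actual) | set(predicted)) - set(classes)
        if unknown:
            raise LabelMismatchError(f"unknown labels {sorted(unknown)}")
    index = {c: i for i, c in enumerate(classes)}
    m = np.zeros((len(classes), len(classes)), dtype=int)
    for a, p in zip(actual, predicted):
        m[index[p], index[a]] += 1
    return ConfusionMatrix(counts=pd.DataFrame(m, index=classes, columns=classes))


def color_feature_subset(n_colors: int) -> list[str]:
    """The 6k feature names of the k most frequent palette colors."""
    if not 1 <= n_colors <= N_PALETTE:
        raise ValueError(f"n_colors must be in 1..{N_PALETTE}")
    return list(COLOR_FEATURE_NAMES[: 6 * n_colors])


def colors_vs_accuracy(table: LabeledFeatureTable, config: CVConfig,
                       max_colors: int = N_PALETTE) -> dict[int, float]:
    """CV accuracy using only the k most frequent colors, k = 1..max_colors.

    Reproduces the design of the colors-only experiment: no non-color
    features are included at any k.
    """
    missing = [c for c in COLOR_FEATURE_NAMES if c not in table.X.columns]
    if missing:
        raise ValueError(f"table lacks color feature columns: {missing[:6]}")
    result: dict[int, float] = {}
    for k in range(1, max_colors + 1):
        sub = table.subset_columns(color_feature_subset(k))
        result[k] = repeated_holdout_cv(sub, config).mean_accuracy
    return result


def variable_importance(table: LabeledFeatureTable,
                        config: CVConfig) -> pd.Series:
    """Random-forest impurity importance of every variable, descending.

    Trains one forest on the full (scaled) table; used to ask which
    variables — color channels, stripe counts or Procrustes shape
    coordinates — carry the class signal.
    """
    rf_config = CVConfig(n_reps=1, seed=config.seed, classifier="rf",
                         rf_mtry=config.rf_mtry, rf_n_trees=config.rf_n_trees)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scaled, _ = scale_features(table, feature_range=config.scale_range)
    model = train_classifier(scaled, rf_config)
    imp = pd.Series(model.feature_importances_, index=table.X.columns)
    return imp.sort_values(ascending=False)
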