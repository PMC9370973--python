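"""Literature comparators: a fixed-threshold signal-similarity classifier and
a pulse-wise skewness-only SVM.

The similarity classifier predicts "good" when the SigSim index (correlation
between consecutive pulses) is at or above a threshold fitted on training
data by the equal-sensitivity/specificity criterion: among all candidate
thresholds (midpoints between consecutive sorted unique scores, plus
sentinels below and above the score range), choose the one minimizing
|Sens - Spec|, ties toward the smaller threshold.

The skewness SVM re-uses the main hyperparameter-tuning harness with the
single ``Skewness`` feature as input.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from ppgqc.classify import MetricsReport, TaskSpec, evaluate, train_model
from ppgqc.exceptions import ConfigurationError, TaskError

SIMILARITY_FEATURE = "SigSim"


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    lo = u[0] - 1.0
    hi = u[-1] + 1.0
    return np.r_[lo, mids, hi]


def fit_equal_sens_spec_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold minimizing |Sens - Spec| on training scores (positives are
    scores >= threshold); ties break toward the smaller candidate."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise TaskError("both classes are required to fit a threshold")
    if np.unique(scores).size == 1:
        warnings.warn("all scores identical; degenerate threshold", stacklevel=2)
        return float(scores[0])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    best_thr, best_gap = None, np.inf
    for thr in _candidate_thresholds(scores):
        pred = scores >= thr
        sens = np.sum(pred & (y == 1)) / n_pos
        spec = np.sum(~pred & (y == 0)) / n_neg
        gap = abs(sens - spec)
        if gap < best_gap:  # strict: ties keep the smaller threshold
            best_thr, best_gap = float(thr), gap
    return best_thr


class SimilarityThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Fixed-threshold classifier on one score column (default SigSim);
    higher scores mean better quality.  Fitted attribute: ``threshold_``."""

    def __init__(self, feature: str = SIMILARITY_FEATURE):
        self.feature = feature

    def fit(self, X, y):
        scores = self._scores(X)
        self.threshold_ = fit_equal_sens_spec_threshold(scores, y)
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        return (self._scores(X) >= self.threshold_).astype(int)

    def decision_scores(self, X) -> np.ndarray:
        return self._scores(X)

    def _scores(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            if self.feature not in X.columns:
                raise ConfigurationError(f"feature column {self.feature!r} missing")
            return X[self.feature].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        return X.ravel() if X.ndim > 1 else X


def similarity_threshold_baseline(
    task: TaskSpec, train_features: pd.DataFrame, train_labels, test_features, test_labels
) -> tuple[SimilarityThresholdClassifier, MetricsReport]:
    """Fit and score the similarity-threshold comparator on one task."""
    clf = SimilarityThresholdClassifier().fit(
        train_features, task.binarize(np.asarray(train_labels))
    )
    return clf, evaluate(clf, test_features, task.binarize(np.asarray(test_labels)))


def skewness_svm_baseline(
    task: TaskSpec,
    train_features: pd.DataFrame,
    train_labels,
    test_features: pd.DataFrame,
    test_labels,
    cv_folds: int = 10,
    opt_iters: int = 30,
    seed: int = 0,
    search: str = "smbo",
) -> tuple[object, MetricsReport]:
    """SVM on the single Skewness column, tuned with the main harness."""
    for frame in (train_features, test_features):
        if "Skewness" not in frame.columns:
            raise ConfigurationError("feature column 'Skewness' missing")
    model = train_model(
        task,
        "svm",
        train_features[["Skewness"]],
        train_labels,
        cv_folds=cv_folds,
        opt_iters=opt_iters,
        seed=seed,
        search=search,
    )
    report = evaluate(
        model, test_features[["Skewness"]], task.binarize(np.asarray(test_labels))
    )
    return model, report
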