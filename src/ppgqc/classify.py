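"""Quality-classifier training, the cascade, and evaluation metrics.

Three binary tasks are built from the consensus B/F/E labels:

* ``BQ``  (basic quality):   F&E (positive) vs B — heart-rate grade;
* ``HQ1`` (high quality, single stage): E vs B&F;
* ``HQ2`` (high quality, cascaded):     E vs F, fed with the pulses the BQ
  stage accepted.

Six model families are supported (decision tree, naive Bayes, support vector
machine, k-nearest neighbours, ensemble, neural network); hyperparameters
are tuned by sequential model-based optimization of the ten-fold
cross-validated misclassification rate, then the winner is refitted on the
full training partition.  Splitting is subject-wise so no wearer contributes
pulses to both partitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KernelDensity, KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from ppgqc import tuning
from ppgqc.exceptions import IntegrityError, ParameterError, TaskError
from ppgqc.tuning import Categorical, Integer, Real

FAMILIES = ("tree", "naive_bayes", "svm", "knn", "ensemble", "neural_net")


@dataclass(frozen=True)
class TaskSpec:
    """One binary quality-classification task over B/F/E consensus labels."""

    name: str
    positive: frozenset
    negative: frozenset

    def admits(self, labels: np.ndarray) -> np.ndarray:
        pool = self.positive | self.negative
        return np.isin(labels, list(pool))

    def binarize(self, labels: np.ndarray) -> np.ndarray:
        labels = np.asarray(labels)
        if not self.admits(labels).all():
            raise TaskError(f"labels outside task {self.name} classes")
        return np.isin(labels, list(self.positive)).astype(int)


TASKS: dict[str, TaskSpec] = {
    "BQ": TaskSpec("BQ", frozenset({"F", "E"}), frozenset({"B"})),
    "HQ1": TaskSpec("HQ1", frozenset({"E"}), frozenset({"B", "F"})),
    "HQ2": TaskSpec("HQ2", frozenset({"E"}), frozenset({"F"})),
}


def split_subjectwise(
    subjects, train_frac: float = 0.7, seed: int = 0
) -> tuple[list, list]:
    """Partition subject ids into train/test with |train| = round-half-up of
    ``train_frac * n``; every pulse follows its subject."""
    subjects = sorted(set(subjects))
    if len(subjects) < 2:
        raise ParameterError("need at least 2 subjects to split")
    n_train = int(math.floor(train_frac * len(subjects) + 0.5))
    n_train = min(max(n_train, 1), len(subjects) - 1)
    order = np.random.default_rng(seed).permutation(len(subjects))
    train = [subjects[i] for i in sorted(order[:n_train])]
    test = [subjects[i] for i in sorted(order[n_train:])]
    return train, test


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with per-class, per-feature Gaussian kernel densities
    (the kernel-density alternative to the Gaussian fit)."""

    def __init__(self, bandwidth: float = 0.5):
        self.bandwidth = bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, counts = np.unique(y, return_counts=True)
        self.log_prior_ = np.log(counts / counts.sum())
        self.kdes_ = []
        for c in self.classes_:
            Xc = X[y == c]
            self.kdes_.append(
                [
                    KernelDensity(bandwidth=self.bandwidth).fit(Xc[:, [j]])
                    for j in range(X.shape[1])
                ]
            )
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        ll = np.tile(self.log_prior_, (len(X), 1))
        for k in range(len(self.classes_)):
            for j, kde in enumerate(self.kdes_[k]):
                ll[:, k] += kde.score_samples(X[:, [j]])
        return ll

    def predict_proba(self, X):
        ll = self._joint_log_likelihood(X)
        ll -= ll.max(axis=1, keepdims=True)
        p = np.exp(ll)
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]


def _search_space(family: str):
    if family == "tree":
        return [Integer("max_depth", 1, 32), Integer("min_samples_leaf", 1, 64, log=True)]
    if family == "naive_bayes":
        return [
            Categorical("density", ("gaussian", "kernel")),
            Real("bandwidth", 0.05, 2.0, log=True),
        ]
    if family == "svm":
        return [
            Categorical("kernel", ("linear", "quadratic", "cubic", "rbf")),
            Real("C", 1e-3, 1e3, log=True),
            Real("kernel_scale", 1e-2, 1e2, log=True),
        ]
    if family == "knn":
        return [
            Integer("n_neighbors", 1, 64, log=True),
            Categorical("metric", ("euclidean", "manhattan")),
            Categorical("weights", ("uniform", "distance")),
        ]
    if family == "ensemble":
        return [
            Categorical("method", ("bagging", "adaboost", "gentleboost")),
            Integer("n_estimators", 50, 500, log=True),
            Real("learning_rate", 1e-2, 1.0, log=True),
        ]
    if family == "neural_net":
        return [
            Integer("hidden_units", 4, 128, log=True),
            Real("alpha", 1e-6, 1e-1, log=True),
        ]
    raise ParameterError(f"unknown family {family!r}")


def _build_estimator(family: str, params: dict, seed: int):
    if family == "tree":
        return DecisionTreeClassifier(
            max_depth=params["max_depth"],
            min_samples_leaf=params["min_samples_leaf"],
            random_state=seed,
        )
    if family == "naive_bayes":
        if params["density"] == "gaussian":
            return GaussianNB()
        return KernelNaiveBayes(bandwidth=params["bandwidth"])
    if family == "svm":
        kernel = params["kernel"]
        gamma = 1.0 / params["kernel_scale"] ** 2
        # iteration cap bounds the cost of pathological (C, scale) proposals
        common = dict(C=params["C"], random_state=seed, max_iter=200_000)
        if kernel == "linear":
            return SVC(kernel="linear", **common)
        if kernel in ("quadratic", "cubic"):
            degree = 2 if kernel == "quadratic" else 3
            return SVC(kernel="poly", degree=degree, gamma=gamma, coef0=1.0, **common)
        return SVC(kernel="rbf", gamma=gamma, **common)
    if family == "knn":
        return KNeighborsClassifier(
            n_neighbors=params["n_neighbors"],
            metric=params["metric"],
            weights=params["weights"],
        )
    if family == "ensemble":
        method = params["method"]
        n = params["n_estimators"]
        if method == "bagging":
            return BaggingClassifier(
                estimator=DecisionTreeClassifier(random_state=seed),
                n_estimators=n,
                random_state=seed,
            )
        if method == "adaboost":
            return AdaBoostClassifier(
                n_estimators=n, learning_rate=params["learning_rate"], random_state=seed
            )
        return GradientBoostingClassifier(
            n_estimators=n, learning_rate=params["learning_rate"], random_state=seed
        )
    if family == "neural_net":
        return MLPClassifier(
            hidden_layer_sizes=(params["hidden_units"],),
            alpha=params["alpha"],
            max_iter=400,
            random_state=seed,
        )
    raise ParameterError(f"unknown family {family!r}")


class QualityClassifier(BaseEstimator, ClassifierMixin):
    """One model family with sequential model-based hyperparameter tuning.

    Parameters
    ----------
    family : str
        One of ``tree, naive_bayes, svm, knn, ensemble, neural_net``.
    cv_folds : int
        Folds for the tuning cross-validation (default ten).
    opt_iters : int
        Sequential evaluations of the optimizer (default 30).
    search : str
        ``"smbo"`` (Gaussian-process expected improvement) or ``"random"``.
    random_state : int
        Seed for folds, optimizer and estimator.

    Fitted attributes: ``best_params_``, ``cv_loss_`` (mean tuning
    misclassification of the winner), ``estimator_`` (refitted on the full
    training partition), ``classes_``, ``feature_names_``.
    """

    def __init__(
        self,
        family: str = "svm",
        cv_folds: int = 10,
        opt_iters: int = 30,
        search: str = "smbo",
        random_state: int = 0,
    ):
        self.family = family
        self.cv_folds = cv_folds
        self.opt_iters = opt_iters
        self.search = search
        self.random_state = random_state

    def fit(self, X, y):
        X, self.feature_names_ = _to_matrix(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise TaskError("training data contains a single class")
        self.classes_ = classes
        folds = min(self.cv_folds, int(min(np.bincount(np.searchsorted(classes, y)))))
        folds = max(folds, 2)
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=self.random_state)

        def objective(params: dict) -> float:
            est = _build_estimator(self.family, params, self.random_state)
            acc = cross_val_score(est, X, y, cv=cv, scoring="accuracy", n_jobs=1)
            return 1.0 - float(acc.mean())

        space = _search_space(self.family)
        self.best_params_, self.cv_loss_, self.history_ = tuning.minimize(
            objective,
            space,
            n_iter=self.opt_iters,
            seed=self.random_state,
            method=self.search,
        )
        self.estimator_ = _build_estimator(
            self.family, self.best_params_, self.random_state
        ).fit(X, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "estimator_")
        X, names = _to_matrix(X)
        self._check_features(names)
        return self.estimator_.predict(X)

    def decision_scores(self, X) -> np.ndarray:
        """Continuous score for ranking/AUC: positive-class probability where
        the family provides one, signed margin otherwise."""
        check_is_fitted(self, "estimator_")
        X, names = _to_matrix(X)
        self._check_features(names)
        if hasattr(self.estimator_, "predict_proba"):
            return np.asarray(self.estimator_.predict_proba(X))[:, -1]
        return np.asarray(self.estimator_.decision_function(X))

    def _check_features(self, names) -> None:
        if names is not None and self.feature_names_ is not None:
            if list(names) != list(self.feature_names_):
                raise IntegrityError(
                    "feature columns do not match the model's training features"
                )


def _to_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


def train_model(
    task: TaskSpec | str,
    family: str,
    train_features,
    train_labels,
    cv_folds: int = 10,
    opt_iters: int = 30,
    seed: int = 0,
    search: str = "smbo",
) -> QualityClassifier:
    """Binarize B/F/E labels for ``task`` and fit one tuned family."""
    task = TASKS[task] if isinstance(task, str) else task
    y = task.binarize(np.asarray(train_labels))
    clf = QualityClassifier(
        family=family,
        cv_folds=cv_folds,
        opt_iters=opt_iters,
        search=search,
        random_state=seed,
    )
    return clf.fit(train_features, y)


class CascadeQualityClassifier:
    """Two-stage grading: BQ rejects Bad pulses, HQ2 splits the survivors
    into Fair and Excellent.  A BQ-negative pulse is graded B regardless of
    the second stage."""

    def __init__(self, bq, hq2):
        self.bq = bq
        self.hq2 = hq2

    def predict(self, X) -> np.ndarray:
        bq_pos = np.asarray(self.bq.predict(X)).astype(bool)
        out = np.full(len(X), "B", dtype=object)
        if bq_pos.any():
            X_pos = X.loc[bq_pos] if isinstance(X, pd.DataFrame) else X[bq_pos]
            hq_pos = np.asarray(self.hq2.predict(X_pos)).astype(bool)
            sub = np.where(hq_pos, "E", "F")
            out[np.flatnonzero(bq_pos)] = sub
        return out.astype(str)


def cascade_predict(bq, hq2, pulses) -> np.ndarray:
    return CascadeQualityClassifier(bq, hq2).predict(pulses)


@dataclass
class MetricsReport:
    """The eight evaluation metrics plus the confusion counts they derive
    from.  AUC is NaN when the test labels contain a single class."""

    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    acc: float = field(init=False)
    sens: float = field(init=False)
    spec: float = field(init=False)
    prec: float = field(init=False)
    mcc: float = field(init=False)
    f1: float = field(init=False)
    kappa: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, tn, fn = (float(v) for v in (self.tp, self.fp, self.tn, self.fn))
        total = tp + fp + tn + fn
        self.acc = (tp + tn) / total if total else float("nan")
        self.sens = tp / (tp + fn) if tp + fn else float("nan")
        self.spec = tn / (tn + fp) if tn + fp else float("nan")
        self.prec = tp / (tp + fp) if tp + fp else float("nan")
        denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        self.mcc = (tp * tn - fp * fn) / denom if denom else float("nan")
        self.f1 = (
            2 * self.prec * self.sens / (self.prec + self.sens)
            if (self.prec + self.sens)
            else float("nan")
        )
        # Cohen's kappa from the confusion counts
        p_obs = self.acc
        p_yes = ((tp + fp) / total) * ((tp + fn) / total) if total else float("nan")
        p_no = ((tn + fn) / total) * ((tn + fp) / total) if total else float("nan")
        p_e = p_yes + p_no
        self.kappa = (p_obs - p_e) / (1 - p_e) if (1 - p_e) else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "AUC": self.auc,
            "Acc": self.acc,
            "Sens": self.sens,
            "Spec": self.spec,
            "Prec": self.prec,
            "MCC": self.mcc,
            "F1": self.f1,
            "kappa": self.kappa,
            "TP": self.tp,
            "FP": self.fp,
            "TN": self.tn,
            "FN": self.fn,
        }


def metrics_from_confusion(tp: int, fp: int, tn: int, fn: int, auc: float = float("nan")):
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc)


def evaluate(model, test_features, test_labels) -> MetricsReport:
    """Score a fitted binary model on held-out pulses (labels already 0/1)."""
    y = np.asarray(test_labels).astype(int)
    pred = np.asarray(model.predict(test_features)).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    if np.unique(y).size < 2:
        auc = float("nan")
    elif hasattr(model, "decision_scores"):
        auc = float(roc_auc_score(y, model.decision_scores(test_features)))
    elif hasattr(model, "predict_proba"):
        auc = float(roc_auc_score(y, model.predict_proba(test_features)[:, -1]))
    elif hasattr(model, "decision_function"):
        auc = float(roc_auc_score(y, model.decision_function(test_features)))
    else:
        auc = float(roc_auc_score(y, pred))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, auc=auc)
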