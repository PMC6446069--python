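"""Classifier backends, stratified k-fold cross-validation, and node metrics.

Backends mirror the classifier sweep of the motivating study: random forest
(the default and overall winner there), Gaussian naive Bayes, and SVMs with
linear, cubic-polynomial and RBF kernels.  Evaluation is canonical stratified
10-fold cross-validation — every sample is predicted exactly once from a model
that never saw it — with class balancing applied inside each training fold by
default so synthetic samples never reach a test fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from survtree.imbalance import BalanceSpec, balance_training

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("random_forest", "naive_bayes", "svm_linear", "svm_poly3", "svm_rbf")


@dataclass
class ClassifierSpec:
    kind: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    predictions: dict[str, int] = field(default_factory=dict)  # sample id -> predicted label

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    undefined: list[str] = field(default_factory=list)  # metrics hit by a 0/0


def make_classifier(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec (seeded, weight-aware)."""
    hp = dict(spec.hyperparameters)
    if spec.kind == "random_forest":
        hp.setdefault("n_estimators", 100)
        hp.setdefault("max_features", "sqrt")
        return RandomForestClassifier(random_state=spec.seed, **hp)
    if spec.kind == "naive_bayes":
        return GaussianNB(**hp)
    if spec.kind == "svm_linear":
        hp.setdefault("C", 1.0)
        return SVC(kernel="linear", random_state=spec.seed, **hp)
    if spec.kind == "svm_poly3":
        hp.setdefault("C", 1.0)
        hp.setdefault("degree", 3)
        return SVC(kernel="poly", random_state=spec.seed, **hp)
    hp.setdefault("C", 1.0)
    hp.setdefault("gamma", "auto")  # 1 / n_features
    return SVC(kernel="rbf", random_state=spec.seed, **hp)


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    sample_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Fit the backend on the training view and predict labels for the test view."""
    y_train = np.asarray(y_train, dtype=int)
    if np.unique(y_train).size < 2:
        raise ValueError("training set contains a single class")
    clf = make_classifier(spec)
    if sample_weight is not None:
        clf.fit(X_train, y_train, sample_weight=sample_weight)
    else:
        clf.fit(X_train, y_train)
    return np.asarray(clf.predict(X_test), dtype=int)


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment tolerating classes smaller than k.

    Within each class, sample order is shuffled (seeded) and assigned round-robin
    to folds, so a 6-sample class spreads at most one sample per fold; folds
    without a positive test sample simply contribute negatives.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment = np.empty(labels.size, dtype=int)
    offset = 0
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        idx = idx[rng.permutation(idx.size)]
        assignment[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size  # stagger classes so small classes don't pile on fold 0
    return assignment


def compute_metrics(confusion: ConfusionSummary) -> Metrics:
    """Accuracy, sensitivity, specificity, precision, F1 from pooled fold counts.

    A 0/0 (e.g. no true positives in the data) reports the metric as 0.0 and
    records its name in ``undefined``, so tabular reports stay numeric.
    """
    tp, fp, tn, fn = confusion.tp, confusion.fp, confusion.tn, confusion.fn
    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = ratio(tp + tn, tp + fp + tn + fn, "accuracy")
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    if precision + sensitivity == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return Metrics(accuracy, sensitivity, specificity, precision, f1, undefined)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    sample_ids: list[str],
    spec: ClassifierSpec,
    balance: BalanceSpec,
    k: int = 10,
    seed: int = 0,
    balance_before_cv: bool = False,
) -> tuple[ConfusionSummary, Metrics]:
    """Stratified k-fold CV of a binary node (positive label = 1).

    Default mode balances each training fold only; ``balance_before_cv=True``
    instead balances once up front and cross-validates the augmented data,
    reproducing the workbench-style protocol of the motivating study (optimistic
    because synthetic points derived from test samples leak into training).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if min(np.bincount(y, minlength=2)) == 0:
        raise ValueError("both classes must be present")
    if k < 2:
        raise ValueError("k must be >= 2")

    eval_ids = list(sample_ids)
    if balance_before_cv:
        bt = balance_training(X, y, balance, seed=balance.seed)
        X, y = bt.X, bt.y
        eval_ids = eval_ids + [f"synthetic_{i}" for i in range(len(bt.y) - len(eval_ids))]
        balance = BalanceSpec(method="none")

    folds = stratified_folds(y, k, seed)
    predicted = np.full(y.size, -1, dtype=int)
    for fold in range(k):
        test_mask = folds == fold
        if not test_mask.any():
            continue
        train_mask = ~test_mask
        bt = balance_training(
            X[train_mask], y[train_mask], balance, seed=balance.seed + fold
        )
        predicted[test_mask] = fit_predict(spec, bt.X, bt.y, X[test_mask], bt.sample_weight)

    assert np.all(predicted >= 0), "every sample must be predicted exactly once"
    tp = int(np.sum((predicted == 1) & (y == 1)))
    fp = int(np.sum((predicted == 1) & (y == 0)))
    tn = int(np.sum((predicted == 0) & (y == 0)))
    fn = int(np.sum((predicted == 0) & (y == 1)))
    confusion = ConfusionSummary(
        tp, fp, tn, fn, {s: int(p) for s, p in zip(eval_ids, predicted)}
    )
    return confusion, compute_metrics(confusion)
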