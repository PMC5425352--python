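"""Condition / creativity-group discrimination and its metric suite.

Binary classification of feature-table rows with either an RBF-kernel SVM
or the from-scratch Sugeno ANFIS (:mod:`.anfis`), evaluated over repeated
stratified 70/30 splits (default 20 runs).  Features are z-scored with
statistics fitted on the training split only.  Reported metrics follow the
diagnostic-test convention:

    accuracy, sensitivity, specificity (percent),
    LR+ = sensitivity / (100 - specificity),
    LR- = (100 - sensitivity) / specificity,
    error rate = 100 - accuracy.

LR+ is unbounded when specificity is 100%; such cells are reported as the
marker ``">100"`` by the formatter rather than infinity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .anfis import anfis_classify, anfis_train


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.7
    n_runs: int = 20
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class DataSplit:
    X_train: np.ndarray
    y_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


def run_seed(spec: SplitSpec, run_index: int) -> int:
    """Deterministic per-run sub-seed derived from (seed, run_index)."""
    return (spec.seed * 1000003 + 7919 * run_index + 1) % (2**31 - 1)


def split_train_test(
    X: np.ndarray, y: np.ndarray, spec: SplitSpec, run_index: int = 0
) -> DataSplit:
    """Stratified random train/test split for one evaluation run."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if np.any(counts < 2):
        lacking = classes[counts < 2].tolist()
        raise ValueError(f"classes with fewer than 2 rows: {lacking}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        train_size=spec.train_fraction,
        random_state=run_seed(spec, run_index),
        stratify=y if spec.stratified else None,
        shuffle=True,
    )
    return DataSplit(X_tr, y_tr, X_te, y_te)


def _check_finite(X: np.ndarray, feature_names: Optional[Sequence[str]] = None) -> None:
    bad = ~np.all(np.isfinite(X), axis=0)
    if np.any(bad):
        if feature_names is not None:
            cols = [feature_names[i] for i in np.flatnonzero(bad)]
        else:
            cols = np.flatnonzero(bad).tolist()
        raise ValueError(f"non-finite values in feature columns: {cols}")


def svm_rbf(
    split: DataSplit,
    C: float = 1.0,
    gamma: str | float = "scale",
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """RBF-kernel SVM predictions on the test split.

    Features are z-scored using training-split statistics only.
    """
    _check_finite(split.X_train, feature_names)
    _check_finite(split.X_test, feature_names)
    scaler = StandardScaler().fit(split.X_train)
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(scaler.transform(split.X_train), split.y_train)
    return clf.predict(scaler.transform(split.X_test))


def anfis_rbf(
    split: DataSplit,
    n_epochs: int = 300,
    cluster_radius: float = 0.5,
    n_rules: Optional[int] = 6,
    feature_names: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """ANFIS predictions on the test split (targets coded {0, 1})."""
    _check_finite(split.X_train, feature_names)
    _check_finite(split.X_test, feature_names)
    scaler = StandardScaler().fit(split.X_train)
    classes = np.unique(split.y_train)
    if classes.size != 2:
        raise ValueError("ANFIS classification requires exactly 2 classes")
    y01 = (split.y_train == classes[1]).astype(float)
    model = anfis_train(
        scaler.transform(split.X_train), y01,
        n_epochs=n_epochs, cluster_radius=cluster_radius, n_rules=n_rules,
    )
    pred01 = anfis_classify(model, scaler.transform(split.X_test))
    return classes[pred01]


@dataclass
class ClassifierReport:
    """Diagnostic metrics, in percent (LR+/LR- dimensionless)."""

    accuracy: float
    sensitivity: float
    specificity: float
    lr_pos: float  # inf when specificity == 100
    lr_neg: float
    error_rate: float
    per_run: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "error_rate": self.error_rate,
        }


def format_lr(value: float, bound: float = 100.0) -> str:
    """Render a likelihood ratio; unbounded / huge cells as '>100'."""
    if not np.isfinite(value) or value > bound:
        return f">{bound:g}"
    return f"{value:.2f}"


def evaluate(predictions: np.ndarray, truth: np.ndarray, positive_label) -> ClassifierReport:
    """Single-run confusion-matrix metrics."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth differ in length")
    pos = truth == positive_label
    if not np.any(pos) or np.all(pos):
        raise ValueError("truth must contain both the positive and negative class")
    tp = int(np.sum((predictions == positive_label) & pos))
    fn = int(np.sum((predictions != positive_label) & pos))
    tn = int(np.sum((predictions != positive_label) & ~pos))
    fp = int(np.sum((predictions == positive_label) & ~pos))
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / truth.size
    lr_pos = sens / (100.0 - spec) if spec < 100.0 else float("inf")
    lr_neg = (100.0 - sens) / spec if spec > 0 else float("inf")
    return ClassifierReport(
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        error_rate=100.0 - acc,
    )


def repeated_evaluation(
    X: np.ndarray,
    y: np.ndarray,
    spec: SplitSpec = SplitSpec(),
    classifier: str = "svm",
    positive_label=None,
    feature_names: Optional[Sequence[str]] = None,
    **params,
) -> ClassifierReport:
    """Mean metrics over ``spec.n_runs`` repeated stratified splits.

    ``positive_label`` defaults to the larger of the two class labels.
    LR means are taken over the runs in which they are finite; if no run is
    finite the mean is reported as infinity (rendered '>100').
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("repeated_evaluation requires exactly 2 classes")
    if positive_label is None:
        positive_label = classes[-1]
    runs = []
    for run_index in range(spec.n_runs):
        split = split_train_test(X, y, spec, run_index)
        if classifier == "svm":
            preds = svm_rbf(split, feature_names=feature_names, **params)
        elif classifier == "anfis":
            preds = anfis_rbf(split, feature_names=feature_names, **params)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        runs.append(evaluate(preds, split.y_test, positive_label).to_dict())
    per_run = pd.DataFrame(runs)

    def _mean(col: str) -> float:
        vals = per_run[col].to_numpy()
        finite = vals[np.isfinite(vals)]
        return float(np.mean(finite)) if finite.size else float("inf")

    return ClassifierReport(
        accuracy=_mean("accuracy"),
        sensitivity=_mean("sensitivity"),
        specificity=_mean("specificity"),
        lr_pos=_mean("lr_pos"),
        lr_neg=_mean("lr_neg"),
        error_rate=_mean("error_rate"),
        per_run=per_run,
    )
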