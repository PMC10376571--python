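"""Gesture classification: LDA / SVM / KNN with stratified CV and
one-vs-rest confusion-matrix metrics.

The classifiers themselves come from scikit-learn; what is authored here
is the study protocol — stratified 70/30 split, 5-fold grid-searched
cross-validation over the hyperparameter families named for each model,
and the per-class sensitivity/specificity/accuracy metrics computed from
the one-vs-rest reduction of the multiclass confusion matrix:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + FP + TN + FN)

Grid order is simple-first, so ties in mean CV accuracy resolve to the
simpler configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

MODEL_KINDS = ("LDA", "SVM", "KNN")


@dataclass
class TrainConfig:
    test_fraction: float = 0.30
    cv_folds: int = 5
    seed: int = 0
    #: optional per-model grid overrides ({"SVM": [...], ...})
    grids: dict[str, list[dict[str, list]]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError(
                f"test_fraction must be in (0, 1), got {self.test_fraction}"
            )
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")


def default_grid(model_kind: str) -> list[dict[str, list]]:
    """Hyperparameter grid per model family, ordered simple-first."""
    if model_kind == "LDA":
        return [{"solver": ["svd"]}, {"solver": ["lsqr"], "shrinkage": [None, "auto"]}]
    if model_kind == "SVM":
        return [
            {"kernel": ["linear"], "C": [0.1, 1.0, 10.0, 100.0]},
            {
                "kernel": ["rbf"],
                "C": [0.1, 1.0, 10.0, 100.0],
                "gamma": ["scale", 0.01, 0.1],
            },
            {
                "kernel": ["poly"],
                "degree": [2, 3, 4],
                "C": [0.1, 1.0, 10.0, 100.0],
                "gamma": ["scale", 0.01, 0.1],
            },
        ]
    if model_kind == "KNN":
        return [
            {
                "n_neighbors": [9, 7, 5, 3, 1],
                "metric": ["euclidean", "manhattan"],
                "algorithm": ["brute", "kd_tree"],
            }
        ]
    raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


def _base_estimator(model_kind: str, seed: int):
    if model_kind == "LDA":
        return LinearDiscriminantAnalysis()
    if model_kind == "SVM":
        return SVC(random_state=seed)
    if model_kind == "KNN":
        return KNeighborsClassifier()
    raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")


def split_dataset(
    X: np.ndarray, y: np.ndarray, config: TrainConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split (default 70/30), deterministic under seed.

    With 250 balanced examples per gesture this yields exactly 175
    training and 75 test examples per class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"smallest class has {counts.min()} examples; need >= {config.cv_folds}"
        )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )
    return X_tr, X_te, y_tr, y_te


@dataclass
class CvResult:
    """Cross-validation summary of the selected configuration."""

    best_params: dict[str, Any]
    fold_scores: np.ndarray
    mean_accuracy: float
    std_accuracy: float
    min_accuracy: float


def tune_and_train(
    model_kind: str, X_train: np.ndarray, y_train: np.ndarray, config: TrainConfig
) -> tuple[Any, CvResult]:
    """Grid-search the model family with stratified k-fold CV, refit the
    best configuration on the full training set."""
    grid = (config.grids or {}).get(model_kind) or default_grid(model_kind)
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        _base_estimator(model_kind, config.seed),
        grid,
        scoring="accuracy",
        cv=cv,
        refit=True,
        n_jobs=1,
    )
    search.fit(X_train, y_train)
    i = search.best_index_
    folds = np.array(
        [search.cv_results_[f"split{k}_test_score"][i] for k in range(config.cv_folds)]
    )
    result = CvResult(
        best_params=search.best_params_,
        fold_scores=folds,
        mean_accuracy=float(folds.mean()),
        std_accuracy=float(folds.std()),
        min_accuracy=float(folds.min()),
    )
    return search.best_estimator_, result


@dataclass
class ConfusionMatrix:
    """K x K confusion matrix, rows = true class, cols = predicted."""

    counts: np.ndarray
    labels: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be K x K for K labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred, labels=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if labels is None:
            labels = sorted(np.unique(np.concatenate([y_true, y_pred])).tolist())
        index = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts=counts, labels=list(labels))

    def one_vs_rest(self, k: int) -> tuple[int, int, int, int]:
        """(TP, TN, FP, FN) for class index k."""
        tp = int(self.counts[k, k])
        fp = int(self.counts[:, k].sum() - tp)
        fn = int(self.counts[k, :].sum() - tp)
        tn = int(self.counts.sum() - tp - fp - fn)
        return tp, tn, fp, fn


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


@dataclass
class ClassReport:
    """Per-class and macro sensitivity / specificity / accuracy."""

    labels: list
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray

    @classmethod
    def from_confusion(cls, cm: ConfusionMatrix) -> "ClassReport":
        sens, spec, acc = [], [], []
        for k in range(len(cm.labels)):
            tp, tn, fp, fn = cm.one_vs_rest(k)
            sens.append(_safe_div(tp, tp + fn))
            spec.append(_safe_div(tn, tn + fp))
            acc.append(_safe_div(tp + tn, tp + fp + tn + fn))
        return cls(
            labels=list(cm.labels),
            sensitivity=np.array(sens),
            specificity=np.array(spec),
            accuracy=np.array(acc),
        )

    @property
    def macro_sensitivity(self) -> float:
        return float(self.sensitivity.mean())

    @property
    def macro_specificity(self) -> float:
        return float(self.specificity.mean())

    @property
    def macro_accuracy(self) -> float:
        return float(self.accuracy.mean())

    def to_dict(self) -> dict:
        return {
            "labels": [str(l) for l in self.labels],
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "accuracy": self.accuracy.tolist(),
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_accuracy": self.macro_accuracy,
        }


def evaluate(model, X_test, y_test, labels=None) -> tuple[ConfusionMatrix, ClassReport]:
    """Confusion matrix and one-vs-rest metric report on held-out data."""
    y_pred = model.predict(np.asarray(X_test, dtype=float))
    cm = ConfusionMatrix.from_predictions(y_test, y_pred, labels=labels)
    return cm, ClassReport.from_confusion(cm)
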