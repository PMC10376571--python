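"""Three-level muscle-fatigue detection from ψ feature vectors.

One small feedforward network is trained per muscular-condition level
(nonfatigue, transition to fatigue, fatigue) as a one-vs-rest binary
detector; at inference the level is the arg-max of the three detector
scores.  Model selection between candidate architectures (1–3 hidden
layers) minimizes the normalized mean square error NMSE = MSE/var(target),
ties broken toward fewer hidden layers.

ROC curves and AUC are computed here by explicit threshold sweeping
(trapezoid rule), so they can be cross-checked against library
implementations in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

LEVELS = (1, 2, 3)
LEVEL_NAMES = {1: "nonfatigue", 2: "transition to fatigue", 3: "fatigue"}


@dataclass
class AnnSpec:
    """Feedforward network architecture for one level detector."""

    hidden_layers: int = 1
    units: int = 16
    activation: str = "logistic"
    epochs: int = 500
    alpha: float = 0.01  # L2 penalty; ~100-dim inputs need real shrinkage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers not in (1, 2, 3):
            raise ValueError(
                f"hidden_layers must be 1, 2 or 3, got {self.hidden_layers}"
            )
        if self.units < 1:
            raise ValueError("units must be >= 1")

    @property
    def hidden_layer_sizes(self) -> tuple[int, ...]:
        return (self.units,) * self.hidden_layers


def nmse(predicted, target) -> float:
    """Normalized mean square error: MSE / var(target).

    0 for a perfect prediction; 1 for predicting the target mean.
    """
    predicted = np.asarray(predicted, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if predicted.shape != target.shape:
        raise ValueError("predicted and target must have the same length")
    v = float(np.var(target))
    if v == 0:
        raise ValueError("target variance is zero; NMSE undefined")
    return float(np.mean((predicted - target) ** 2) / v)


@dataclass
class LevelDetector:
    level: int
    spec: AnnSpec
    model: MLPClassifier
    train_nmse: float

    def score(self, psi: np.ndarray) -> np.ndarray:
        """P(level active) per row of psi."""
        psi = np.atleast_2d(np.asarray(psi, dtype=float))
        pos = list(self.model.classes_).index(1)
        return self.model.predict_proba(psi)[:, pos]


@dataclass
class FatigueDetectorBank:
    """The three one-vs-rest level detectors."""

    detectors: dict[int, LevelDetector]

    def scores(self, psi: np.ndarray) -> np.ndarray:
        """n x 3 matrix of level scores (columns ordered level 1, 2, 3)."""
        psi = np.atleast_2d(np.asarray(psi, dtype=float))
        return np.column_stack([self.detectors[lv].score(psi) for lv in LEVELS])

    def predict_level(self, psi: np.ndarray) -> np.ndarray:
        return np.array(LEVELS)[np.argmax(self.scores(psi), axis=1)]

    @property
    def nmse_per_level(self) -> dict[int, float]:
        return {lv: d.train_nmse for lv, d in self.detectors.items()}


def train_level_detectors(
    psi_matrix: np.ndarray,
    level_labels: np.ndarray,
    specs: dict[int, AnnSpec] | AnnSpec | None = None,
) -> FatigueDetectorBank:
    """Fit one binary detector per level. Deterministic under each spec seed."""
    psi_matrix = np.atleast_2d(np.asarray(psi_matrix, dtype=float))
    level_labels = np.asarray(level_labels)
    present = np.unique(level_labels)
    if present.size < 2:
        raise ValueError("need at least two distinct level labels to train")
    if specs is None:
        specs = AnnSpec()
    if isinstance(specs, AnnSpec):
        specs = {lv: specs for lv in LEVELS}

    detectors: dict[int, LevelDetector] = {}
    for lv in LEVELS:
        spec = specs[lv]
        target = (level_labels == lv).astype(int)
        model = MLPClassifier(
            hidden_layer_sizes=spec.hidden_layer_sizes,
            activation=spec.activation,
            solver="lbfgs",
            alpha=spec.alpha,
            max_iter=spec.epochs,
            random_state=spec.seed + lv,
        )
        model.fit(psi_matrix, target)
        pos = list(model.classes_).index(1)
        scores = model.predict_proba(psi_matrix)[:, pos]
        detectors[lv] = LevelDetector(
            level=lv, spec=spec, model=model, train_nmse=nmse(scores, target)
        )
    return FatigueDetectorBank(detectors=detectors)


def select_model(
    candidates: list[tuple[AnnSpec, float]], criterion: str = "nmse"
) -> AnnSpec:
    """Pick the candidate (spec, nmse) minimizing NMSE; ties favour fewer
    hidden layers."""
    if not candidates:
        raise ValueError("empty candidate list")
    if criterion != "nmse":
        raise ValueError(f"unknown selection criterion {criterion!r}")
    return min(candidates, key=lambda c: (c[1], c[0].hidden_layers))[0]


def roc_curve(
    scores: np.ndarray, binary_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Threshold-swept ROC with trapezoid-rule AUC.

    Returns (fpr, tpr, auc) with endpoints (0,0) and (1,1).  Invariant to
    strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(binary_labels).ravel().astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels for a ROC")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1 - sorted_labels)
    # collapse tied thresholds to their last (cumulative) point
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_scores.size - 1]
    tpr = np.r_[0.0, tp[distinct] / n_pos, 1.0]
    fpr = np.r_[0.0, fp[distinct] / n_neg, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def rank_features(
    psi_matrix: np.ndarray, level_labels: np.ndarray, method: str = "mutual_info"
) -> np.ndarray:
    """Optional feature ranking (indices, most relevant first).

    method ∈ {"mutual_info", "effect_size"}.  Off the default pipeline;
    provided for exploratory relevance analysis of ψ.
    """
    psi_matrix = np.atleast_2d(np.asarray(psi_matrix, dtype=float))
    level_labels = np.asarray(level_labels)
    if method == "mutual_info":
        from sklearn.feature_selection import mutual_info_classif

        rel = mutual_info_classif(psi_matrix, level_labels, random_state=0)
    elif method == "effect_size":
        # max pairwise Cohen's d across level pairs, per feature
        groups = [psi_matrix[level_labels == lv] for lv in np.unique(level_labels)]
        rel = np.zeros(psi_matrix.shape[1])
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                pooled = np.sqrt((a.var(axis=0) + b.var(axis=0)) / 2.0)
                d = np.abs(a.mean(axis=0) - b.mean(axis=0)) / np.maximum(pooled, 1e-30)
                rel = np.maximum(rel, d)
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    return np.argsort(-rel)
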