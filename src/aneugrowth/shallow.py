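"""Classifiers operating on the five morphologic indices.

Three model families:

* a univariate optimal-threshold rule, found by exhaustively scanning
  candidate cut points over the observed feature range and keeping the
  accuracy maximiser;
* a random forest (100 trees, depth 3, information-gain splits,
  aggregated leaf posteriors);
* a multilayer perceptron (two hidden layers of 100 units, cross-entropy
  loss, quasi-Newton optimisation) with per-fold feature standardisation
  — without it, optimisation over mm^3-scale volumes next to unitless
  indices is badly conditioned.

The positive class is *growing* throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .morphology import FEATURE_NAMES


@dataclass
class FeatureMatrix:
    """Cases x the five indices (hmax, volume, surface_area, nsi, ar)."""

    X: np.ndarray            # (n, 5)
    y: np.ndarray            # (n,) 1 = growing, 0 = stable
    case_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[1] != len(FEATURE_NAMES):
            raise ValueError(f"X must have {len(FEATURE_NAMES)} columns")
        if np.isnan(self.X).any():
            raise ValueError("features contain missing values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        cols = ["hmax_mm", "volume_mm3", "surface_area_mm2", "nsi", "ar"]
        return cls(
            X=df[cols].to_numpy(),
            y=df["label"].map({"stable": 0, "growing": 1}).to_numpy()
            if df["label"].dtype == object
            else df["label"].to_numpy(),
            case_ids=list(df["case_id"].astype(str)),
        )

    def column(self, feature: str) -> np.ndarray:
        return self.X[:, FEATURE_NAMES.index(feature)]


@dataclass
class ThresholdModel:
    """Single-feature decision rule; boundary values predict growing."""

    feature_name: str
    threshold: float
    direction: str           # ">=" growing above threshold, "<=" growing below
    train_accuracy: float


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def fit_univariate_threshold(values: np.ndarray, labels: np.ndarray, feature_name: str = "") -> ThresholdModel:
    """Accuracy-maximising threshold over the min-max range of a feature.

    Candidates are the midpoints between consecutive sorted unique values
    plus the extremes, tried in both directions.  Ties are broken toward
    the smaller threshold, then toward the ``>=`` direction.  A value
    exactly at the threshold predicts growing.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(values) < 2:
        raise ValueError("need at least two cases")
    _check_two_classes(labels)
    uniq = np.unique(values)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]])
    best = None
    for t in candidates:
        for direction in (">=", "<="):
            pred = values >= t if direction == ">=" else values <= t
            acc = float(np.mean(pred.astype(int) == labels))
            # lexicographic: accuracy, then smaller threshold, then ">="
            key = (acc, -t, direction == ">=")
            if best is None or key > best[0]:
                best = (key, ThresholdModel(feature_name, float(t), direction, acc))
    return best[1]


def predict_threshold(model: ThresholdModel, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels plus continuous scores (signed distance to threshold).

    Scores are direction-adjusted so larger always means more
    growing-like, suitable for ROC analysis.
    """
    values = np.asarray(values, dtype=float)
    if model.direction == ">=":
        scores = values - model.threshold
    else:
        scores = model.threshold - values
    return (scores >= 0).astype(int), scores


def fit_random_forest(data: FeatureMatrix, seed: int = 0) -> RandomForestClassifier:
    """100 trees of depth 3, entropy splits, bootstrapped; conventional
    defaults elsewhere.  Predicted probabilities average the per-tree
    leaf posteriors."""
    _check_two_classes(data.y)
    clf = RandomForestClassifier(
        n_estimators=100,
        max_depth=3,
        criterion="entropy",
        random_state=seed,
    )
    clf.fit(data.X, data.y)
    return clf


def fit_mlp(data: FeatureMatrix, seed: int = 0, max_iter: int = 500) -> Pipeline:
    """Two hidden layers of 100 units, LBFGS, learning-rate parameter 1e-4,
    with training-fold standardisation in front."""
    _check_two_classes(data.y)
    clf = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(100, 100),
                    solver="lbfgs",
                    learning_rate_init=1e-4,
                    max_iter=max_iter,
                    random_state=seed,
                ),
            ),
        ]
    )
    clf.fit(data.X, data.y)
    return clf


def predict_proba_growing(model, X: np.ndarray) -> np.ndarray:
    """P(growing) from a fitted scikit-learn classifier."""
    proba = model.predict_proba(np.asarray(X, dtype=float))
    classes = list(model.classes_) if hasattr(model, "classes_") else list(model[-1].classes_)
    return proba[:, classes.index(1)]
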