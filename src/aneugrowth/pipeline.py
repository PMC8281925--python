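"""End-to-end glue: cohort -> features -> model specs -> CV report."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .evaluation import (
    FoldAssignment,
    MetricsReport,
    ModelSpec,
    run_cv,
    stratified_folds,
    summarize,
)
from .meshes import LabeledCase
from .morphology import FEATURE_NAMES, compute_features
from .pointcloud import (
    NetworkConfig,
    TrainConfig,
    build_network,
    desk_config,
    desk_train_config,
    predict_cases,
    train,
)
from .shallow import (
    FeatureMatrix,
    fit_mlp,
    fit_random_forest,
    fit_univariate_threshold,
    predict_proba_growing,
    predict_threshold,
)


def cohort_features(cases: Sequence[LabeledCase]) -> FeatureMatrix:
    """Morphologic indices of every dome, as a feature matrix."""
    X = np.stack([compute_features(c.dome).as_array() for c in cases])
    y = np.array([c.y for c in cases], dtype=int)
    return FeatureMatrix(X=X, y=y, case_ids=[c.case_id for c in cases])


def cohort_labels(cases: Sequence[LabeledCase]) -> np.ndarray:
    return np.array([c.y for c in cases], dtype=int)


def threshold_spec(features: FeatureMatrix, feature: str) -> ModelSpec:
    """Cross-validated univariate threshold model for one index."""
    if feature not in FEATURE_NAMES:
        raise ValueError(f"unknown feature {feature!r}")
    values = features.column(feature)

    def fit_predict(train_idx, test_idx, seed):
        del seed
        model = fit_univariate_threshold(values[train_idx], features.y[train_idx], feature)
        _, scores = predict_threshold(model, values[test_idx])
        return scores

    return ModelSpec(name=feature, fit_predict=fit_predict)


def rf_spec(features: FeatureMatrix) -> ModelSpec:
    def fit_predict(train_idx, test_idx, seed):
        sub = FeatureMatrix(
            X=features.X[train_idx],
            y=features.y[train_idx],
            case_ids=[features.case_ids[i] for i in train_idx],
        )
        clf = fit_random_forest(sub, seed=seed)
        return predict_proba_growing(clf, features.X[test_idx])

    return ModelSpec(name="rf", fit_predict=fit_predict)


def mlp_spec(features: FeatureMatrix) -> ModelSpec:
    def fit_predict(train_idx, test_idx, seed):
        sub = FeatureMatrix(
            X=features.X[train_idx],
            y=features.y[train_idx],
            case_ids=[features.case_ids[i] for i in train_idx],
        )
        clf = fit_mlp(sub, seed=seed)
        return predict_proba_growing(clf, features.X[test_idx])

    return ModelSpec(name="mlp", fit_predict=fit_predict)


def pointcloud_spec(
    cases: Sequence[LabeledCase],
    net_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
    use_vasculature: bool = False,
) -> ModelSpec:
    net_config = net_config or desk_config()
    train_config = train_config or desk_train_config()
    name = "pointcloud_vasculature" if use_vasculature else "pointcloud"

    def fit_predict(train_idx, test_idx, seed):
        tc = TrainConfig(
            learning_rate=train_config.learning_rate,
            momentum=train_config.momentum,
            weight_decay=train_config.weight_decay,
            batch_size=train_config.batch_size,
            epochs=train_config.epochs,
            seed=seed,
        )
        model = build_network(net_config, seed=seed)
        train(model, [cases[i] for i in train_idx], tc, use_vasculature=use_vasculature)
        return predict_cases(
            model, [cases[i] for i in test_idx], use_vasculature=use_vasculature, seed=seed
        )

    return ModelSpec(name=name, fit_predict=fit_predict)


def univariate_insample(features: FeatureMatrix, feature: str) -> np.ndarray:
    """Scores of the threshold model fitted on all cases (the in-sample
    protocol used for comparability; optimistically biased)."""
    model = fit_univariate_threshold(features.column(feature), features.y, feature)
    _, scores = predict_threshold(model, features.column(feature))
    return scores


def evaluate_models(
    cases: Sequence[LabeledCase],
    specs: Sequence[ModelSpec],
    k: int = 4,
    seed: int = 0,
    folds: FoldAssignment | None = None,
) -> tuple[list[MetricsReport], dict[str, np.ndarray], FoldAssignment]:
    """Run each model through the same stratified CV and summarise."""
    labels = cohort_labels(cases)
    if folds is None:
        folds = stratified_folds(labels, k=k, seed=seed)
    reports, scores_by_model = [], {}
    for spec in specs:
        scores = run_cv(labels, spec, folds, seed=seed)
        scores_by_model[spec.name] = scores
        reports.append(summarize(spec.name, scores, labels, folds))
    return reports, scores_by_model, folds
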