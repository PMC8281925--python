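"""Cross-validated evaluation of growth-prediction models.

The protocol: stratified k-fold split (default 4), per-fold training
with identical hyperparameters, aggregation of out-of-fold scores, then
ROC/AUC plus the best-accuracy operating point with its sensitivity and
specificity.  Growing is the positive class: sensitivity is the growing
detection rate.  The operating point is selected on the aggregated test
scores and is therefore labelled a post-hoc operating point — it is an
optimistically biased summary, reported for comparability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve


@dataclass
class FoldAssignment:
    fold_of: np.ndarray  # (n,) fold index per case
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def stratified_folds(labels: Sequence[int], k: int = 4, seed: int = 0) -> FoldAssignment:
    """Round-robin stratified assignment.

    Cases are permuted within each class and dealt onto folds with a
    counter that carries across classes, so fold sizes differ by at most
    one overall and per class.  With 44 cases split 25/19 and k = 4 this
    yields four folds of exactly 11 cases.
    """
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} cases")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    counter = 0
    for cls in (1, 0):  # positive class dealt first
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        for i in idx:
            fold_of[i] = counter % k
            counter += 1
    return FoldAssignment(fold_of=fold_of, k=k)


# ---------------------------------------------------------------------------
# ROC / operating point


@dataclass
class ROCResult:
    thresholds: np.ndarray  # decreasing score cut-points (leading +inf)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_and_auc(scores: Sequence[float], labels: Sequence[int]) -> ROCResult:
    """ROC by sweeping all score thresholds; AUC by the trapezoid rule.

    Tied scores are grouped into a single ROC vertex, which makes the
    trapezoidal AUC equal to the Mann-Whitney concordance probability
    with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapezoid_auc(fpr, tpr)))


def best_accuracy_point(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, threshold) maximising accuracy.

    All thresholds of the form "predict growing when score >= t" are
    enumerated; accuracy ties break toward higher sensitivity (missing a
    future-growing aneurysm is the costlier error).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    uniq = np.unique(scores)
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, uniq, [np.inf]])
    best = None
    for t in np.sort(candidates):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        accuracy = (tp + tn) / len(labels)
        sens = tp / n_pos
        spec = tn / n_neg
        key = (accuracy, sens)
        if best is None or key > best[0]:
            best = (key, (accuracy, sens, spec, float(t)))
    return best[1]


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class ModelSpec:
    """A named model with a fit-and-score closure over the cohort.

    ``fit_predict(train_idx, test_idx, fold_seed)`` must train from
    scratch on the training cases and return continuous growing-scores
    for the test cases.
    """

    name: str
    fit_predict: Callable[[np.ndarray, np.ndarray, int], np.ndarray]


def run_cv(
    labels: Sequence[int],
    spec: ModelSpec,
    folds: FoldAssignment,
    seed: int = 0,
) -> np.ndarray:
    """k train/test runs with identical hyperparameters; every case
    receives exactly one out-of-fold score."""
    labels = np.asarray(labels, dtype=int)
    scores = np.full(len(labels), np.nan)
    for fold in range(folds.k):
        train_idx = folds.train_indices(fold)
        test_idx = folds.test_indices(fold)
        try:
            s = np.asarray(spec.fit_predict(train_idx, test_idx, seed), dtype=float)
        except Exception as exc:
            raise RuntimeError(f"model {spec.name!r} failed in fold {fold}: {exc}") from exc
        if s.shape != test_idx.shape:
            raise RuntimeError(f"model {spec.name!r} returned wrong score count in fold {fold}")
        scores[test_idx] = s
    assert not np.isnan(scores).any()
    return scores


# ---------------------------------------------------------------------------
# reporting


@dataclass
class MetricsReport:
    model: str
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    per_fold: list[dict] = field(default_factory=list)


def summarize(
    name: str,
    scores: Sequence[float],
    labels: Sequence[int],
    folds: FoldAssignment | None = None,
) -> MetricsReport:
    """Aggregate metrics plus (optionally) a per-fold breakdown."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    roc = roc_and_auc(scores, labels)
    accuracy, sens, spec, _thr = best_accuracy_point(scores, labels)
    report = MetricsReport(
        model=name, auc=roc.auc, accuracy=accuracy, sensitivity=sens, specificity=spec
    )
    if folds is not None:
        for fold in range(folds.k):
            idx = folds.test_indices(fold)
            if len(np.unique(labels[idx])) < 2:
                continue
            froc = roc_and_auc(scores[idx], labels[idx])
            facc, fsens, fspec, _ = best_accuracy_point(scores[idx], labels[idx])
            report.per_fold.append(
                {
                    "fold": fold,
                    "auc": froc.auc,
                    "accuracy": facc,
                    "sensitivity": fsens,
                    "specificity": fspec,
                }
            )
    return report


def report(
    results: Sequence[MetricsReport],
    scores_by_model: dict[str, np.ndarray] | None = None,
    labels: Sequence[int] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Machine-readable summary: one "all" row per model plus fold rows.

    When ``out_dir`` is given, writes report.json, report.csv and (when
    scores are provided) roc_curves.csv with the ROC polylines.
    """
    if len(results) == 0:
        raise ValueError("at least one model result is required")
    rows = []
    for r in results:
        rows.append(
            {
                "model": r.model,
                "test_data": "all",
                "auc": r.auc,
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
        )
        for f in r.per_fold:
            rows.append(
                {
                    "model": r.model,
                    "test_data": f"fold {f['fold'] + 1}",
                    "auc": f["auc"],
                    "accuracy": f["accuracy"],
                    "sensitivity": f["sensitivity"],
                    "specificity": f["specificity"],
                }
            )
    table = pd.DataFrame(rows)
    payload = {"models": [asdict(r) for r in results]}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        out.joinpath("report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        table.to_csv(out / "report.csv", index=False)
        if scores_by_model is not None and labels is not None:
            roc_rows = []
            for name, scores in scores_by_model.items():
                roc = roc_and_auc(scores, labels)
                for f, t in zip(roc.fpr, roc.tpr):
                    roc_rows.append({"model": name, "fpr": f, "tpr": t})
            pd.DataFrame(roc_rows).to_csv(out / "roc_curves.csv", index=False)
    return payload, table


def plot_roc(scores_by_model: dict[str, np.ndarray], labels: Sequence[int], path: str | Path) -> None:
    """ROC curves for all models on one panel (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, scores in scores_by_model.items():
        roc = roc_and_auc(scores, labels)
        ax.plot(roc.fpr, roc.tpr, label=f"{name} (AUC = {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate (sensitivity)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
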