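"""Per-class ROC/AUC, best-model selection, stacking, metric reports and
the longitudinal class-proportion trend.

Per-class scores come from the multiclass softmax one-vs-rest: the class's
probability is the positive score, everything else is "rest". Stacking
fits, per class, a logistic meta-classifier over the base models'
one-vs-rest scores; its training data must be disjoint from the base
models' training beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .synth import CLASSES

__all__ = [
    "ROCResult",
    "MetricsReport",
    "EnsembleSpec",
    "roc_auc",
    "macro_ovr_auc",
    "select_best_models",
    "fit_stacker",
    "stacker_predict",
    "metrics_report",
    "class_trend",
]

#: deterministic ordering of model kinds for AUC tie-breaking
_KIND_ORDER = {"cnn": 0, "gru": 1, "lstm": 2, "vgg13": 0, "crnn_bigru": 1, "crnn_bilstm": 2}


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve by threshold sweep over the unique scores, AUC by
    trapezoid. Tied scores flip together (one threshold per unique score).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if labels.all() or (~labels).all():
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = _roc_curve(labels, scores, drop_intermediate=False)
    return ROCResult(thr, fpr, tpr, float(_trapezoid_auc(fpr, tpr)))


def macro_ovr_auc(probs: np.ndarray, labels: np.ndarray) -> float:
    """Macro mean of the one-vs-rest AUCs over the five classes (classes
    absent from ``labels`` are skipped)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    aucs = []
    for c in range(probs.shape[1]):
        pos = labels == c
        if pos.any() and (~pos).any():
            aucs.append(roc_auc(probs[:, c], pos).auc)
    if not aucs:
        raise ValueError("no class with both positives and negatives")
    return float(np.mean(aucs))


def select_best_models(
    auc_table: dict[tuple[str, str, int], float]
) -> dict[str, tuple[str, int]]:
    """Per-class argmax of AUC over (model kind, n_mels).

    Keys of ``auc_table`` are (class, kind, n_mels). Ties break toward the
    smaller feature count, then CNN < GRU < LSTM, so selection is
    deterministic.
    """
    per_class: dict[str, list] = {}
    for (cls, kind, n_mels), value in auc_table.items():
        per_class.setdefault(cls, []).append((value, n_mels, kind))
    missing = [c for c in CLASSES if c not in per_class]
    if missing:
        raise ValueError(f"classes absent from AUC table: {missing}")
    chosen = {}
    for cls, entries in per_class.items():
        entries.sort(key=lambda e: (-e[0], e[1], _KIND_ORDER.get(e[2], 99)))
        best = entries[0]
        chosen[cls] = (best[2], best[1])
    return chosen


@dataclass
class EnsembleSpec:
    """Per-class base-model choice plus per-class logistic stackers."""

    base_models: dict[str, str]  # class -> base model identifier
    stackers: dict[str, LogisticRegression] = field(default_factory=dict)
    model_ids: tuple[str, ...] = ()

    def predict(self, base_scores: dict[str, np.ndarray]) -> np.ndarray:
        return stacker_predict(self, base_scores)


def _stack_features(base_scores: dict[str, np.ndarray], model_ids, class_idx: int):
    return np.column_stack([base_scores[m][:, class_idx] for m in model_ids])


def fit_stacker(
    base_scores: dict[str, np.ndarray],
    labels: np.ndarray,
    seed: int = 0,
    base_models: dict[str, str] | None = None,
    base_train_ids=None,
    beat_ids=None,
) -> EnsembleSpec:
    """Fit per-class logistic meta-classifiers over base-model scores.

    ``base_scores`` maps a model identifier to an (N, 5) probability array
    on the stacking fold. If ``base_train_ids`` and ``beat_ids`` are given,
    any overlap (a beat used both to train a base model and to fit the
    stacker) is an error.
    """
    if base_train_ids is not None and beat_ids is not None:
        leaked = set(np.asarray(base_train_ids).tolist()) & set(
            np.asarray(beat_ids).tolist()
        )
        if leaked:
            raise ValueError(f"beats leaked from base training into stacking: {sorted(leaked)[:5]}")
    labels = np.asarray(labels, dtype=int)
    model_ids = tuple(sorted(base_scores))
    if base_models is None:
        base_models = {cls: model_ids[0] for cls in CLASSES}
    spec = EnsembleSpec(base_models=dict(base_models), model_ids=model_ids)
    for c, cls in enumerate(CLASSES):
        y = (labels == c).astype(int)
        feats = _stack_features(base_scores, model_ids, c)
        if y.min() == y.max():
            # class absent (or universal) on this fold: fall back to the
            # chosen base model's score via an identity-like stacker
            spec.stackers[cls] = None
            continue
        clf = LogisticRegression(max_iter=1000, random_state=seed)
        clf.fit(feats, y)
        spec.stackers[cls] = clf
    return spec


def stacker_predict(
    spec: EnsembleSpec, base_scores: dict[str, np.ndarray], renormalize: bool = True
) -> np.ndarray:
    """Stacked five-class scores.

    With ``renormalize`` (default) rows sum to 1 and the result is a valid
    prediction vector; without it each column is the raw per-class meta
    probability, a monotone function of that class's base scores (the form
    to use for per-class ROC analysis, since renormalization couples the
    classes).
    """
    n = next(iter(base_scores.values())).shape[0]
    out = np.zeros((n, len(CLASSES)))
    for c, cls in enumerate(CLASSES):
        clf = spec.stackers.get(cls)
        feats = _stack_features(base_scores, spec.model_ids, c)
        if clf is None:
            out[:, c] = base_scores[spec.base_models.get(cls, spec.model_ids[0])][:, c]
        else:
            out[:, c] = clf.predict_proba(feats)[:, 1]
    if not renormalize:
        return out
    total = out.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    return out / total


@dataclass(frozen=True)
class MetricsReport:
    """Per-class accuracy/precision/recall/specificity/F1/AUC plus macro means."""

    table: pd.DataFrame  # rows = metrics, columns = classes + "mean"

    METRICS = ("accuracy", "precision", "recall", "specificity", "f1", "auc")

    def __getitem__(self, key: tuple[str, str]) -> float:
        metric, cls = key
        return float(self.table.loc[metric, cls])


def metrics_report(
    probs: np.ndarray,
    labels: np.ndarray,
    thresholds: dict[str, float] | None = None,
) -> MetricsReport:
    """One-vs-rest confusion per class and the six standard metrics.

    Default assignment rule is the softmax argmax; ``thresholds`` switches
    class ``c`` to the rule ``P(c) > threshold[c]`` (useful to trade recall
    for a lower false-positive rate on rare classes).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("predictions and labels must align")
    argmax = probs.argmax(axis=1)
    cols = {}
    for c, cls in enumerate(CLASSES):
        actual_pos = labels == c
        if thresholds is not None and cls in thresholds:
            pred_pos = probs[:, c] > thresholds[cls]
        else:
            pred_pos = argmax == c
        tp = int(np.sum(pred_pos & actual_pos))
        fp = int(np.sum(pred_pos & ~actual_pos))
        fn = int(np.sum(~pred_pos & actual_pos))
        tn = int(np.sum(~pred_pos & ~actual_pos))
        accuracy = (tp + tn) / max(tp + tn + fp + fn, 1)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        if actual_pos.any() and (~actual_pos).any():
            auc_c = roc_auc(probs[:, c], actual_pos).auc
        else:
            auc_c = np.nan
        cols[cls] = [accuracy, precision, recall, specificity, f1, auc_c]
    table = pd.DataFrame(cols, index=list(MetricsReport.METRICS))
    table["mean"] = table.mean(axis=1, skipna=True)
    return MetricsReport(table)


def class_trend(daily_beat_predictions: dict) -> pd.DataFrame:
    """Longitudinal class-proportion trend over consultation dates.

    ``daily_beat_predictions`` maps a date to an (N, 5) array of per-beat
    probabilities. Returns one row per (date, class) with the mean class
    probability and the share of beats whose argmax is that class, sorted
    chronologically — the view used to follow a fistula's sound profile
    (e.g., rising intermittent/harmonic share after puncture begins).
    """
    if not daily_beat_predictions:
        raise ValueError("need at least one date")
    rows = []
    for date in sorted(daily_beat_predictions):
        probs = np.asarray(daily_beat_predictions[date], dtype=float)
        if probs.ndim != 2 or probs.shape[1] != len(CLASSES):
            raise ValueError(f"predictions for {date!r} must be (N, 5)")
        argmax = probs.argmax(axis=1)
        for c, cls in enumerate(CLASSES):
            rows.append(
                {
                    "date": date,
                    "class": cls,
                    "mean_probability": float(probs[:, c].mean()),
                    "argmax_share": float(np.mean(argmax == c)),
                }
            )
    return pd.DataFrame(rows)
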