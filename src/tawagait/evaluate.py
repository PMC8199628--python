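"""Cross-validated evaluation of the full pipeline.

The protocol mirrors a standard wearable-sensor study: 5-fold
cross-validation, accuracy / macro-precision / macro-recall / macro-F1 per
fold, and a pooled confusion matrix built from the concatenated labels and
predictions of all folds.  Folds are assigned at the *trial* level,
stratified by (subject, activity): sliding windows from one trial overlap
heavily, so any sample-level split would leak between train and test.

Per fold, the scaler and classifier are fitted on training-fold windows
only; test windows are transformed with the training statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .classify import TrainConfig, predict, train
from .features import (
    FeatureMode,
    extract_step_features,
    make_windows,
    normalize,
    windows_to_matrix,
)
from .segment import (
    DEFAULT_MIN_STANCE_SAMPLES,
    DEFAULT_OFF_THRESHOLD,
    DEFAULT_ON_THRESHOLD,
    detect_steps,
)
from .trial import PressureTrial

__all__ = ["EvalReport", "kfold_split", "metrics", "run_protocol"]

logger = logging.getLogger(__name__)


def kfold_split(
    trials: Sequence[PressureTrial], folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Assign each trial a fold in 0..folds-1, stratified by (subject, activity).

    Within each (subject, activity) stratum trials are shuffled (seeded) and
    dealt round-robin, so folds are balanced within ±1 trial per stratum.
    Strata with fewer trials than folds get a best-effort assignment with a
    warning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if len(trials) < folds:
        raise ValueError(f"need at least {folds} trials, got {len(trials)}")

    rng = np.random.default_rng(seed)
    assignment = np.full(len(trials), -1, dtype=int)
    strata: dict[tuple[int, int], list[int]] = {}
    for i, t in enumerate(trials):
        strata.setdefault((t.subject_id, int(t.activity)), []).append(i)

    offset = 0  # rotate starting fold across strata for global balance
    for key in sorted(strata):
        idx = np.array(strata[key])
        if len(idx) < folds:
            warnings.warn(
                f"stratum {key} has {len(idx)} trials < {folds} folds; "
                "best-effort assignment",
                stacklevel=2,
            )
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            assignment[i] = (j + offset) % folds
        offset += len(idx) % folds
    return assignment


def _contingency(
    y_true: np.ndarray, y_pred: np.ndarray, labels: Sequence[int]
) -> dict:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # absent classes handled as zeros
        prec, rec, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0, average=None
        )
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "precision": float(prec.mean()),
        "recall": float(rec.mean()),
        "f1": float(f1.mean()),
        "per_class_precision": prec,
        "per_class_recall": rec,
        "per_class_f1": f1,
        "confusion": cm,
    }


def metrics(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    labels: Sequence[int] | None = None,
) -> dict:
    """Accuracy, macro precision/recall/F1 and the confusion matrix.

    Macro averages weight every class equally; classes never predicted get
    precision 0 (conservative, deterministic).  ``labels`` fixes the class
    set (default: union of true and predicted labels, sorted).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    return _contingency(y_true, y_pred, list(labels))


@dataclass
class EvalReport:
    """Pooled cross-validation result for one (task, window length)."""

    task: str  # "activity" | "pedestrian"
    k: int
    feature_mode: str
    labels: list[int]
    fold_metrics: list[dict] = field(default_factory=list)
    pooled_confusion: np.ndarray | None = None
    pooled_metrics: dict = field(default_factory=dict)
    n_windows: int = 0

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "k": self.k,
            "feature_mode": self.feature_mode,
            "labels": self.labels,
            "n_windows": self.n_windows,
            "fold_metrics": [
                {m: round(fm[m], 10) for m in ("accuracy", "precision", "recall", "f1")}
                for fm in self.fold_metrics
            ],
            "pooled_metrics": {
                m: round(self.pooled_metrics[m], 10)
                for m in ("accuracy", "precision", "recall", "f1")
            },
            "pooled_confusion": self.pooled_confusion.tolist(),
        }


def run_protocol(
    trials: Sequence[PressureTrial],
    task: str,
    k_values: Sequence[int],
    feature_mode: FeatureMode = "tawa+std",
    train_config: TrainConfig | None = None,
    folds: int = 5,
    seed: int = 0,
    min_stance_samples: int = DEFAULT_MIN_STANCE_SAMPLES,
    on_threshold: int = DEFAULT_ON_THRESHOLD,
    off_threshold: int = DEFAULT_OFF_THRESHOLD,
    delta_t: int = 1,
    feet: str = "stance",
) -> dict[int, EvalReport]:
    """Full pipeline evaluation: segment → features → windows → CV → report.

    Steps and their features are computed once per trial; for each window
    length k the windows are rebuilt and, per fold, a scaler and classifier
    are fitted on the training fold only.  Returns one report per k.
    """
    if task not in ("activity", "pedestrian"):
        raise ValueError("task must be 'activity' or 'pedestrian'")
    train_config = train_config or TrainConfig()

    step_features = []
    for trial in trials:
        segs = detect_steps(trial, min_stance_samples, on_threshold, off_threshold)
        step_features.append(extract_step_features(trial, segs, delta_t, feet=feet))

    fold_of_trial = kfold_split(trials, folds=folds, seed=seed)

    reports: dict[int, EvalReport] = {}
    for k in k_values:
        windows, window_fold = [], []
        for fold, steps in zip(fold_of_trial, step_features):
            w = make_windows(steps, k, mode=feature_mode)
            windows.extend(w)
            window_fold.extend([fold] * len(w))
        if not windows:
            raise ValueError(
                f"no samples: no trial has at least k={k} detected steps"
            )
        window_fold = np.array(window_fold)
        X, y_act, y_subj = windows_to_matrix(windows)
        y = y_act if task == "activity" else y_subj
        labels = sorted(int(v) for v in np.unique(y))

        report = EvalReport(
            task=task, k=k, feature_mode=feature_mode, labels=labels,
            n_windows=len(windows),
        )
        pooled_true, pooled_pred = [], []
        for fold in range(folds):
            test = window_fold == fold
            if not test.any() or test.all():
                logger.warning("fold %d has an empty side; skipped", fold)
                continue
            X_train, sc = normalize(X[~test])
            X_test = sc.transform(X[test])
            cfg = TrainConfig(**{**train_config.__dict__, "seed": train_config.seed + fold})
            model = train(X_train, y[~test], cfg)
            y_pred = predict(model, X_test)
            report.fold_metrics.append(metrics(y[test], y_pred, labels))
            pooled_true.append(y[test])
            pooled_pred.append(np.asarray(y_pred))

        pooled = metrics(np.concatenate(pooled_true), np.concatenate(pooled_pred), labels)
        report.pooled_metrics = pooled
        report.pooled_confusion = pooled["confusion"]
        reports[k] = report
        logger.info(
            "%s k=%d: pooled accuracy %.4f over %d windows",
            task, k, pooled["accuracy"], report.n_windows,
        )
    return reports
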