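"""Temporally adaptive weighting accumulation (TAWA) features.

For the stance of one step, let ``P_i[k]`` be the level of sensor *i* at
stance sample ``k = 1..T`` (samples re-indexed per step).  The feature
family accumulates each sensor's pressure under three temporal weightings:

* **TIWA** (temporally increasing):   ``f1(i) = (1/T) Σ_k P_i[k] · k`` —
  weights grow with time, emphasising late stance (pre-swing / toe-off).
* **TDWA** (temporally decreasing):   ``f2(i) = (1/T) Σ_k P_i[k] / k`` —
  inverse-time weights emphasise early stance (initial contact).
* **TIdWA** (time-independent):       ``f3(i) = (1/T) Σ_k P_i[k]`` —
  the per-step mean, the overall pressure distribution.

A fourth descriptor, the per-sensor population standard deviation over the
stance, captures pressure variation within the step.  Up to the common 1/T
normalisation, TIWA/TDWA are (scaled) expectations E[t] and E[1/t] of the
pressure-mass distribution over stance time, so the pair encodes *when*
each sensor is loaded while TIdWA encodes *how much*.

Downstream, the four 8-vectors of k consecutive steps are concatenated
into one sliding-window classification sample (stride one step), and
feature matrices are z-scored with statistics fitted on training data only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .segment import StepSegment, slice_stance
from .trial import Activity, N_SENSORS, PressureTrial

__all__ = [
    "StepFeatures",
    "WindowSample",
    "Scaler",
    "tiwa",
    "tdwa",
    "tidwa",
    "stdfeat",
    "extract_step_features",
    "normalize",
    "make_windows",
    "FEATURE_GROUPS",
]

#: feature-group order inside a step's block (and in CSV exports)
FEATURE_GROUPS = ("tiwa", "tdwa", "tidwa", "std")

FeatureMode = Literal["tawa", "tawa+std"]


def _check_stance(stance: np.ndarray) -> np.ndarray:
    s = np.asarray(stance, dtype=float)
    if s.ndim != 2 or s.shape[0] != N_SENSORS:
        raise ValueError(f"stance must be ({N_SENSORS}, T), got {s.shape}")
    if s.shape[1] < 1:
        raise ValueError("empty stance (T = 0)")
    return s


def _weights_index(T: int, delta_t: int) -> np.ndarray:
    if delta_t < 1 or delta_t > T:
        raise ValueError(f"delta_t must be in 1..T, got {delta_t} (T={T})")
    return np.arange(delta_t, T + 1, dtype=float)


def tiwa(stance: np.ndarray, delta_t: int = 1) -> np.ndarray:
    """Temporally increasing weighting accumulation, one value per sensor.

    ``delta_t`` is the first stance sample included (per-step local index,
    default 1 = the whole stance).
    """
    s = _check_stance(stance)
    T = s.shape[1]
    k = _weights_index(T, delta_t)
    return s[:, delta_t - 1 :] @ k / T


def tdwa(stance: np.ndarray, delta_t: int = 1) -> np.ndarray:
    """Temporally decreasing (inverse-time) weighting accumulation."""
    s = _check_stance(stance)
    T = s.shape[1]
    k = _weights_index(T, delta_t)
    return s[:, delta_t - 1 :] @ (1.0 / k) / T


def tidwa(stance: np.ndarray, delta_t: int = 1) -> np.ndarray:
    """Time-independent accumulation: the per-step mean level per sensor."""
    s = _check_stance(stance)
    T = s.shape[1]
    return s[:, delta_t - 1 :].sum(axis=1) / T


def stdfeat(stance: np.ndarray) -> np.ndarray:
    """Per-sensor population standard deviation (divisor T) over the stance."""
    s = _check_stance(stance)
    return s.std(axis=1, ddof=0)


@dataclass(frozen=True)
class StepFeatures:
    """The four 8-vectors of one step, with carried labels."""

    trial_id: str
    step_index: int
    subject_id: int
    activity: Activity
    tiwa: np.ndarray
    tdwa: np.ndarray
    tidwa: np.ndarray
    std: np.ndarray

    def block(self, mode: FeatureMode = "tawa+std") -> np.ndarray:
        """Concatenated per-step feature vector (24 for tawa, 32 with std)."""
        parts = [self.tiwa, self.tdwa, self.tidwa]
        if mode == "tawa+std":
            parts.append(self.std)
        elif mode != "tawa":
            raise ValueError(f"unknown feature mode {mode!r}")
        return np.concatenate(parts)


def extract_step_features(
    trial: PressureTrial,
    segments: Sequence[StepSegment],
    delta_t: int = 1,
    feet: Literal["stance", "both"] = "stance",
) -> list[StepFeatures]:
    """Compute the feature family on each segment's stance foot, in order.

    ``feet="both"`` appends the contralateral foot's 8 sensors over the same
    stance window, doubling each feature vector to 16 entries.
    """
    if feet not in ("stance", "both"):
        raise ValueError(f"feet must be 'stance' or 'both', got {feet!r}")
    out = []
    for seg in segments:
        parts = [slice_stance(trial, seg)]  # raises on trial mismatch
        if feet == "both":
            other = "right" if seg.foot == "left" else "left"
            parts.append(trial.foot(other)[seg.stance_start : seg.stance_end].T)
        out.append(
            StepFeatures(
                trial_id=trial.trial_id,
                step_index=seg.step_index,
                subject_id=trial.subject_id,
                activity=trial.activity,
                tiwa=np.concatenate([tiwa(p, delta_t) for p in parts]),
                tdwa=np.concatenate([tdwa(p, delta_t) for p in parts]),
                tidwa=np.concatenate([tidwa(p, delta_t) for p in parts]),
                std=np.concatenate([stdfeat(p) for p in parts]),
            )
        )
    return out


@dataclass
class Scaler:
    """Per-dimension z-score transform with training-set statistics.

    Zero-variance dimensions keep scale 1 (centred, not divided), so
    constant columns pass through without blow-up.
    """

    mean: np.ndarray
    scale: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean) / self.scale


def normalize(
    train_features: np.ndarray, apply_to: np.ndarray | None = None
) -> tuple[np.ndarray, Scaler]:
    """Fit a z-score scaler on training rows and apply it.

    Returns ``(transformed, scaler)`` where ``transformed`` is ``apply_to``
    (default: the training matrix itself) in the training frame.  The scaler
    must be fitted on the training fold only and reused on held-out data.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("training feature matrix must be non-empty and 2-D")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    scaler = Scaler(mean=mean, scale=sd)
    target = X if apply_to is None else np.asarray(apply_to, dtype=float)
    return scaler.transform(target), scaler


@dataclass(frozen=True)
class WindowSample:
    """k consecutive steps of one trial as a classification sample."""

    features: np.ndarray  # ordered concatenation of k step blocks
    activity: Activity
    subject_id: int
    trial_id: str
    first_step_index: int
    k: int


def make_windows(
    steps: Iterable[StepFeatures],
    k: int,
    mode: FeatureMode = "tawa+std",
) -> list[WindowSample]:
    """Sliding windows of k consecutive steps, stride 1, never across trials.

    A trial with s >= k steps contributes s - k + 1 windows; shorter trials
    contribute none.  Steps are grouped by trial in input order.
    """
    if k < 1:
        raise ValueError(f"window length k must be >= 1, got {k}")

    by_trial: dict[str, list[StepFeatures]] = {}
    for sf in steps:
        by_trial.setdefault(sf.trial_id, []).append(sf)

    windows: list[WindowSample] = []
    for trial_id, group in by_trial.items():
        group = sorted(group, key=lambda sf: sf.step_index)
        for start in range(len(group) - k + 1):
            chunk = group[start : start + k]
            windows.append(
                WindowSample(
                    features=np.concatenate([sf.block(mode) for sf in chunk]),
                    activity=chunk[0].activity,
                    subject_id=chunk[0].subject_id,
                    trial_id=trial_id,
                    first_step_index=chunk[0].step_index,
                    k=k,
                )
            )
    return windows


def window_feature_names(
    k: int, mode: FeatureMode = "tawa+std", n_sensors: int = N_SENSORS
) -> list[str]:
    """Column names matching the layout of :meth:`StepFeatures.block`.

    ``n_sensors`` is 8 for stance-foot features, 16 when both feet are
    concatenated (sensors 9-16 are the contralateral foot).
    """
    groups = FEATURE_GROUPS if mode == "tawa+std" else FEATURE_GROUPS[:3]
    names = []
    for j in range(1, k + 1):
        prefix = "" if k == 1 else f"step{j}_"
        for g in groups:
            names += [f"{prefix}s{i}_{g}" for i in range(1, n_sensors + 1)]
    return names


def windows_to_frame(windows: Sequence["WindowSample"], mode: FeatureMode = "tawa+std"):
    """Feature matrix as a DataFrame: label columns first, then features."""
    import pandas as pd

    if not windows:
        raise ValueError("no window samples")
    k = windows[0].k
    X = np.stack([w.features for w in windows])
    n_groups = 4 if mode == "tawa+std" else 3
    n_sensors = X.shape[1] // (k * n_groups)
    frame = pd.DataFrame(X, columns=window_feature_names(k, mode, n_sensors))
    frame.insert(0, "first_step_index", [w.first_step_index for w in windows])
    frame.insert(0, "trial_id", [w.trial_id for w in windows])
    frame.insert(0, "subject_id", [w.subject_id for w in windows])
    frame.insert(0, "activity", [int(w.activity) for w in windows])
    return frame


def windows_to_matrix(
    windows: Sequence[WindowSample],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into (X, activity labels, subject labels)."""
    if not windows:
        raise ValueError("no window samples")
    X = np.stack([w.features for w in windows])
    y_act = np.array([int(w.activity) for w in windows])
    y_subj = np.array([w.subject_id for w in windows])
    return X, y_act, y_subj
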