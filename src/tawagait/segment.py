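"""Step detection and stance-phase segmentation.

Steps are detected per foot from the summed 8-sensor level signal with a
hysteresis threshold: a stance opens when the sum rises to at least
``on_threshold`` and closes at the first later sample whose sum falls to
``off_threshold`` or below.  Hysteresis makes the detector robust to
single-sensor jitter on categorical data, where the foot sum lives on a
small integer grid (0..24).  Runs shorter than ``min_stance_samples`` are
discarded as contact artifacts.  Each foot is segmented independently
(double-support samples belong to both feet's stances); the two feet's
segments are merged in stance-start order to form the step sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial import PressureTrial

__all__ = ["StepSegment", "detect_steps", "slice_stance"]

DEFAULT_ON_THRESHOLD = 3
DEFAULT_OFF_THRESHOLD = 1
DEFAULT_MIN_STANCE_SAMPLES = 5  # 0.1 s at 50 Hz


@dataclass(frozen=True)
class StepSegment:
    """One detected step: a half-open stance interval on one foot."""

    trial_id: str
    step_index: int
    foot: str  # "left" | "right"
    stance_start: int  # inclusive
    stance_end: int  # exclusive

    def __post_init__(self) -> None:
        if self.foot not in ("left", "right"):
            raise ValueError(f"foot must be 'left' or 'right', got {self.foot!r}")
        if not self.stance_start < self.stance_end:
            raise ValueError("stance_start must be < stance_end")

    @property
    def T(self) -> int:
        """Number of stance samples."""
        return self.stance_end - self.stance_start


def _foot_runs(
    foot_sum: np.ndarray, on_threshold: int, off_threshold: int
) -> list[tuple[int, int]]:
    """Half-open [start, end) runs under the hysteresis rule."""
    runs: list[tuple[int, int]] = []
    start = None
    for t, s in enumerate(foot_sum):
        if start is None:
            if s >= on_threshold:
                start = t
        elif s <= off_threshold:
            runs.append((start, t))
            start = None
    if start is not None:  # trial ends mid-stance
        runs.append((start, len(foot_sum)))
    return runs


def detect_steps(
    trial: PressureTrial,
    min_stance_samples: int = DEFAULT_MIN_STANCE_SAMPLES,
    on_threshold: int = DEFAULT_ON_THRESHOLD,
    off_threshold: int = DEFAULT_OFF_THRESHOLD,
) -> list[StepSegment]:
    """Detect stance segments on both feet and merge them into a step order.

    Returns an empty list (not an error) when the trial contains no stance.
    Simultaneous stance starts are ordered left before right so the output
    is deterministic.
    """
    if on_threshold < off_threshold or off_threshold < 0:
        raise ValueError("need on_threshold >= off_threshold >= 0")
    if min_stance_samples < 1:
        raise ValueError("min_stance_samples must be >= 1")

    candidates: list[tuple[int, int, str]] = []
    for foot in ("left", "right"):
        foot_sum = trial.foot(foot).sum(axis=1)
        for start, end in _foot_runs(foot_sum, on_threshold, off_threshold):
            if end - start >= min_stance_samples:
                candidates.append((start, end, foot))

    candidates.sort(key=lambda c: (c[0], c[2] != "left"))
    return [
        StepSegment(
            trial_id=trial.trial_id,
            step_index=i,
            foot=foot,
            stance_start=start,
            stance_end=end,
        )
        for i, (start, end, foot) in enumerate(candidates)
    ]


def slice_stance(trial: PressureTrial, seg: StepSegment) -> np.ndarray:
    """Return the stance foot's 8 sensor rows over the stance, shape (8, T)."""
    if seg.trial_id != trial.trial_id:
        raise ValueError(
            f"segment belongs to trial {seg.trial_id!r}, not {trial.trial_id!r}"
        )
    if seg.stance_start < 0 or seg.stance_end > trial.n_samples:
        raise IndexError(
            f"stance [{seg.stance_start}, {seg.stance_end}) outside trial of "
            f"{trial.n_samples} samples"
        )
    return trial.foot(seg.foot)[seg.stance_start : seg.stance_end].T
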