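"""Canonical data model and plain-text I/O for categorical plantar-pressure trials.

A trial is one recording of a subject performing one ambulatory activity
(level walk, stair ascent or stair descent) while wearing a pair of
instrumented insoles.  Each insole carries 8 pressure sensors that report
an ordinal level in {0, 1, 2, 3} ("no", "slight", "moderate", "high"
pressure) at a nominal 50 Hz.

On disk a cohort is a long-format CSV, one row per time sample, columns
``trial_id, subject_id, activity, t_index, L1..L8, R1..R8`` (UTF-8, comma
separated), or the equivalent JSON list of trial records.  Sensor indices
follow the insole layout convention declared in :data:`SENSOR_LAYOUT`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Activity",
    "PressureTrial",
    "SENSOR_LAYOUT",
    "N_SENSORS",
    "LEVELS",
    "read_trials",
    "write_trials",
]

N_SENSORS = 8
LEVELS = (0, 1, 2, 3)

#: Anatomical role of each sensor index (0-based).  The hardware numbers
#: sensors 1-8; by convention sensors 1-2 sit under the toes/forefoot and
#: 7-8 under the heel.  This mapping is a declared convention, used by the
#: simulator to sweep activation heel-to-toe; every other stage is agnostic.
SENSOR_LAYOUT = {
    0: "toe",
    1: "toe",
    2: "forefoot",
    3: "forefoot",
    4: "midfoot",
    5: "midfoot",
    6: "heel",
    7: "heel",
}


class Activity(enum.IntEnum):
    """Ambulatory activity codes (the figure-label convention)."""

    STAIR_DESCENT = 1
    STAIR_ASCENT = 2
    LEVEL_WALK = 3


@dataclass
class PressureTrial:
    """One recording: two synchronous 8-sensor categorical streams.

    Parameters
    ----------
    trial_id
        Unique identifier within the cohort.
    subject_id
        Enrolled subject (1-based).
    activity
        One of :class:`Activity`.
    left, right
        ``(n_samples, 8)`` integer arrays of pressure levels in {0..3},
        time-ordered and uniformly sampled at ``rate_hz``.  Sample ``t``
        has implicit 0-based index ``t_index = t``.
    rate_hz
        Sampling rate, nominally 50 Hz.
    """

    trial_id: str
    subject_id: int
    activity: Activity
    left: np.ndarray
    right: np.ndarray
    rate_hz: float = 50.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        self.activity = Activity(int(self.activity))
        self.validate()

    def validate(self) -> None:
        for name, arr in (("left", self.left), ("right", self.right)):
            if arr.ndim != 2 or arr.shape[1] != N_SENSORS:
                raise ValueError(
                    f"trial {self.trial_id!r}: {name} must be (n, {N_SENSORS}), "
                    f"got {arr.shape}"
                )
            if arr.size and (arr.min() < 0 or arr.max() > 3):
                raise ValueError(
                    f"trial {self.trial_id!r}: {name} has levels outside {{0..3}}"
                )
        if self.left.shape[0] != self.right.shape[0]:
            raise ValueError(
                f"trial {self.trial_id!r}: left/right sample counts differ"
            )
        if self.rate_hz <= 0:
            raise ValueError(f"trial {self.trial_id!r}: rate_hz must be positive")
        if self.subject_id < 1:
            raise ValueError(f"trial {self.trial_id!r}: subject_id must be >= 1")

    @property
    def n_samples(self) -> int:
        return self.left.shape[0]

    def foot(self, side: str) -> np.ndarray:
        if side not in ("left", "right"):
            raise ValueError(f"foot side must be 'left' or 'right', got {side!r}")
        return self.left if side == "left" else self.right

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PressureTrial):
            return NotImplemented
        return (
            self.trial_id == other.trial_id
            and self.subject_id == other.subject_id
            and self.activity == other.activity
            and self.rate_hz == other.rate_hz
            and np.array_equal(self.left, other.left)
            and np.array_equal(self.right, other.right)
        )


_CSV_COLUMNS = (
    ["trial_id", "subject_id", "activity", "t_index"]
    + [f"L{i}" for i in range(1, N_SENSORS + 1)]
    + [f"R{i}" for i in range(1, N_SENSORS + 1)]
)


def _trial_to_frame(trial: PressureTrial) -> pd.DataFrame:
    n = trial.n_samples
    data = {
        "trial_id": np.repeat(trial.trial_id, n),
        "subject_id": np.repeat(trial.subject_id, n),
        "activity": np.repeat(int(trial.activity), n),
        "t_index": np.arange(n, dtype=np.int64),
    }
    for i in range(N_SENSORS):
        data[f"L{i + 1}"] = trial.left[:, i]
    for i in range(N_SENSORS):
        data[f"R{i + 1}"] = trial.right[:, i]
    return pd.DataFrame(data, columns=_CSV_COLUMNS)


def write_trials(
    trials: Sequence[PressureTrial],
    path: str | Path,
    format: str = "csv",
    rate_hz: float | None = None,
) -> None:
    """Serialize trials; the file round-trips through :func:`read_trials`.

    CSV is the canonical dialect (one row per time sample); JSON stores one
    record per trial including ``rate_hz``.  CSV assumes a cohort-wide rate
    (the nominal 50 Hz unless every trial agrees on another value).
    """
    path = Path(path)
    if format == "csv":
        frames = [_trial_to_frame(t) for t in trials]
        if frames:
            df = pd.concat(frames, ignore_index=True)
        else:
            df = pd.DataFrame(columns=_CSV_COLUMNS)
        df.to_csv(path, index=False)
    elif format == "json":
        records = [
            {
                "trial_id": t.trial_id,
                "subject_id": int(t.subject_id),
                "activity": int(t.activity),
                "rate_hz": float(t.rate_hz),
                "left": t.left.tolist(),
                "right": t.right.tolist(),
            }
            for t in trials
        ]
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")


def read_trials(
    path: str | Path, format: str = "csv", rate_hz: float = 50.0
) -> list[PressureTrial]:
    """Load and validate trials written by :func:`write_trials`.

    Raises
    ------
    ValueError
        On missing columns, non-contiguous ``t_index``, or any sensor level
        outside {0..3} (the error names the offending trial/row).
    """
    path = Path(path)
    if format == "json":
        records = json.loads(path.read_text())
        return [
            PressureTrial(
                trial_id=str(r["trial_id"]),
                subject_id=int(r["subject_id"]),
                activity=Activity(int(r["activity"])),
                left=np.asarray(r["left"], dtype=np.int64).reshape(-1, N_SENSORS),
                right=np.asarray(r["right"], dtype=np.int64).reshape(-1, N_SENSORS),
                rate_hz=float(r.get("rate_hz", rate_hz)),
            )
            for r in records
        ]
    if format != "csv":
        raise ValueError(f"unknown format {format!r} (expected 'csv' or 'json')")

    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    sensor_cols = _CSV_COLUMNS[4:]
    levels = df[sensor_cols].to_numpy()
    bad = (levels < 0) | (levels > 3)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0])
        raise ValueError(
            f"{path}: sensor level outside {{0..3}} at data row {row}"
        )

    trials: list[PressureTrial] = []
    # preserve file order of first appearance
    for trial_id, group in df.groupby("trial_id", sort=False):
        group = group.sort_values("t_index")
        t_index = group["t_index"].to_numpy()
        if not np.array_equal(t_index, np.arange(len(group))):
            raise ValueError(
                f"{path}: trial {trial_id!r} has non-contiguous t_index"
            )
        subj = group["subject_id"].unique()
        act = group["activity"].unique()
        if len(subj) != 1 or len(act) != 1:
            raise ValueError(
                f"{path}: trial {trial_id!r} has inconsistent subject/activity"
            )
        trials.append(
            PressureTrial(
                trial_id=str(trial_id),
                subject_id=int(subj[0]),
                activity=Activity(int(act[0])),
                left=group[[f"L{i}" for i in range(1, 9)]].to_numpy(),
                right=group[[f"R{i}" for i in range(1, 9)]].to_numpy(),
                rate_hz=rate_hz,
            )
        )
    return trials
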