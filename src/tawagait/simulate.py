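"""Synthetic categorical plantar-pressure cohorts.

The study data behind this method are not public, so this module generates
multi-subject, multi-activity trials with the structure the method assumes:

* step-periodic pressure bursts on the stance foot, alternating feet;
* a heel-to-toe activation sweep across the 8 sensor positions within each
  stance (initial contact at the heel, pre-swing at the toes);
* per-activity differences in *when* pressure mass falls within the stance
  (early for stair descent, late for stair ascent) and in the spatial
  emphasis across sensors;
* per-subject signatures — a log-normal per-sensor gain vector and a
  stance-duration multiplier drawn once per subject — so identity
  information lives in both amplitude and timing;
* categorical noise (random ±1 level jitter) and quantization of the
  continuous template to the hardware's 4 ordinal levels.

The continuous stance template for sensor *i* is a raised cosine whose
center sweeps from the heel sensors to the toe sensors over the stance.
An activity's temporal skew γ warps the activation centers
``c -> c**(1/γ)``: γ > 1 relocates every activation later in the stance
(mass late, emphasising pre-swing), γ < 1 earlier (mass early, emphasising
initial contact).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trial import Activity, N_SENSORS, PressureTrial

__all__ = ["ActivityProfile", "SimConfig", "simulate_cohort", "quantize"]

#: Quantization thresholds on unit-normalized continuous force.  Fixed,
#: arbitrary values that spread the four levels over the template's range.
DEFAULT_THRESHOLDS = (0.2, 0.5, 0.8)


@dataclass(frozen=True)
class ActivityProfile:
    """Per-activity generator parameters.

    ``emphasis`` scales each sensor's amplitude (index 0 = toe, 7 = heel);
    ``skew`` is the temporal warp exponent γ (>1 late-stance emphasis,
    <1 early-stance emphasis, 1 neutral).
    """

    emphasis: tuple[float, ...]
    skew: float

    def __post_init__(self) -> None:
        if len(self.emphasis) != N_SENSORS:
            raise ValueError("emphasis must have 8 entries")
        if self.skew <= 0:
            raise ValueError("skew must be positive")


# Level walk: neutral timing, mild heel+toe rocker emphasis.
# Stair ascent: push-off dominated — toe emphasis, late mass (γ > 1).
# Stair descent: forefoot landing — early mass (γ < 1), heel unloaded.
DEFAULT_PROFILES: dict[Activity, ActivityProfile] = {
    Activity.LEVEL_WALK: ActivityProfile(
        emphasis=(1.05, 1.05, 1.0, 0.95, 0.9, 0.95, 1.05, 1.05), skew=1.0
    ),
    Activity.STAIR_ASCENT: ActivityProfile(
        emphasis=(1.25, 1.2, 1.1, 1.0, 0.85, 0.75, 0.65, 0.6), skew=1.35
    ),
    Activity.STAIR_DESCENT: ActivityProfile(
        emphasis=(1.15, 1.1, 1.05, 0.95, 0.8, 0.7, 0.55, 0.5), skew=0.75
    ),
}


@dataclass
class SimConfig:
    """Cohort-generation parameters.

    Defaults describe the study conditions the pipeline is evaluated under:
    50 Hz sampling, 12 steps per trial, ~0.45 s stances — a normal walking
    cadence — with subject signatures strong enough to carry identity and
    4-level quantization as the only amplitude information.
    """

    n_subjects: int = 5
    n_trials_per_activity: int = 6
    steps_per_trial: int = 12
    rate_hz: float = 50.0
    stance_duration_s: float = 0.45
    swing_duration_s: float = 0.35
    activity_profiles: Mapping[Activity, ActivityProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    #: log-space SD of the per-subject per-sensor gain (log-normal).
    subject_signature_sd: float = 0.15
    #: SD of the per-subject stance-duration multiplier (around 1.0).
    subject_timing_sd: float = 0.08
    #: per-sample, per-sensor probability of a ±1 level jitter.
    noise_level: float = 0.0
    quant_thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    seed: int = 0

    def __post_init__(self) -> None:
        # accept plain mappings (e.g. YAML-loaded) for profiles/thresholds
        coerced: dict[Activity, ActivityProfile] = {}
        for a, p in self.activity_profiles.items():
            if not isinstance(p, ActivityProfile):
                p = ActivityProfile(emphasis=tuple(p["emphasis"]), skew=float(p["skew"]))
            coerced[Activity(int(a))] = p
        self.activity_profiles = coerced
        self.quant_thresholds = tuple(float(t) for t in self.quant_thresholds)
        missing = [a for a in Activity if a not in self.activity_profiles]
        if missing:
            raise ValueError(f"activity_profiles missing {missing}")
        if self.n_subjects < 1 or self.n_trials_per_activity < 1:
            raise ValueError("n_subjects and n_trials_per_activity must be >= 1")
        if self.steps_per_trial < 1:
            raise ValueError("steps_per_trial must be >= 1")
        if not 0.0 <= self.noise_level <= 1.0:
            raise ValueError("noise_level must be in [0, 1]")
        if self.subject_signature_sd < 0 or self.subject_timing_sd < 0:
            raise ValueError("signature SDs must be non-negative")
        if self.stance_duration_s <= 0 or self.swing_duration_s <= 0:
            raise ValueError("durations must be positive")
        if int(round(self.stance_duration_s * self.rate_hz)) < 4:
            raise ValueError(
                "stance_duration_s * rate_hz must give at least 4 samples"
            )


def quantize(force: float | np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Map continuous non-negative force to an ordinal level in {0,1,2,3}.

    The level is the count of thresholds strictly below the force, i.e.
    force in (t1, t2] -> 1, above t3 -> 3.  Thresholds must be strictly
    ascending.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or thr.size != 3 or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be 3 strictly ascending numbers")
    f = np.asarray(force, dtype=float)
    return (f[..., None] > thr).sum(axis=-1).astype(np.int64)


def _raised_cosine(u: np.ndarray, center: float, half_width: float) -> np.ndarray:
    """0.5*(1+cos) bump on |u-center| <= half_width, zero outside."""
    x = (u - center) / half_width
    out = 0.5 * (1.0 + np.cos(np.pi * np.clip(x, -1.0, 1.0)))
    out[np.abs(x) >= 1.0] = 0.0
    return out


#: fraction of the stance at which each sensor's activation peaks
#: (heel sensors first, toe sensors last — the heel-to-toe rollover).
_SENSOR_PHASE = np.linspace(0.85, 0.15, N_SENSORS)  # index 0 = toe -> late
_ACTIVATION_HALF_WIDTH = 0.45


def _stance_force(
    n_samples: int, emphasis: np.ndarray, skew: float, gains: np.ndarray
) -> np.ndarray:
    """Continuous per-sensor force over one stance, shape (n_samples, 8).

    The skew warps each sensor's activation *center* as ``c -> c**(1/γ)``
    while keeping the bump width: γ > 1 relocates every activation (and
    hence the pressure mass) later in the stance, γ < 1 earlier, and the
    heel-to-toe order is preserved because the warp is monotone.
    """
    u = (np.arange(n_samples) + 0.5) / n_samples  # stance fraction in (0,1)
    centers = _SENSOR_PHASE ** (1.0 / skew)
    force = np.empty((n_samples, N_SENSORS))
    for i in range(N_SENSORS):
        force[:, i] = _raised_cosine(u, centers[i], _ACTIVATION_HALF_WIDTH)
    return force * (emphasis * gains)[None, :]


def _apply_level_noise(
    levels: np.ndarray, noise_level: float, rng: np.random.Generator
) -> np.ndarray:
    if noise_level <= 0:
        return levels
    jitter_mask = rng.random(levels.shape) < noise_level
    jitter = rng.integers(0, 2, size=levels.shape) * 2 - 1  # ±1
    return np.clip(levels + jitter_mask * jitter, 0, 3)


def simulate_cohort(config: SimConfig) -> list[PressureTrial]:
    """Generate ``n_subjects × 3 activities × n_trials_per_activity`` trials.

    Within a trial, steps alternate feet starting with the left foot; step
    k's stance begins at ``k * (stance + swing)/2`` so consecutive opposite
    -foot stances overlap (double support) while same-foot stances never do.
    Swing-phase samples of the moving foot are zero up to noise.  The whole
    cohort is a pure function of ``config`` (bitwise-identical per seed).
    """
    root = np.random.default_rng(config.seed)
    # one child stream per subject for signatures, one per trial for noise
    subj_rng = np.random.default_rng(root.integers(2**31))
    noise_seed = int(root.integers(2**31))

    gains = np.exp(
        subj_rng.normal(0.0, config.subject_signature_sd, (config.n_subjects, N_SENSORS))
    )
    timing = 1.0 + subj_rng.normal(0.0, config.subject_timing_sd, config.n_subjects)
    timing = np.clip(timing, 0.7, 1.3)

    trials: list[PressureTrial] = []
    trial_counter = 0
    for s in range(config.n_subjects):
        for activity in (
            Activity.STAIR_DESCENT,
            Activity.STAIR_ASCENT,
            Activity.LEVEL_WALK,
        ):
            profile = config.activity_profiles[activity]
            emphasis = np.asarray(profile.emphasis, dtype=float)
            stance_n = int(round(config.stance_duration_s * timing[s] * config.rate_hz))
            stance_n = max(stance_n, 4)
            swing_n = int(round(config.swing_duration_s * config.rate_hz))
            step_interval = max((stance_n + swing_n) // 2, stance_n // 2 + 1)
            # same-foot period is 2*step_interval >= stance_n + 2 > stance_n:
            # consecutive stances of one foot never touch.
            n_total = (config.steps_per_trial - 1) * step_interval + stance_n + swing_n

            force_template = _stance_force(stance_n, emphasis, profile.skew, gains[s])
            levels_template = quantize(force_template, config.quant_thresholds)

            for rep in range(config.n_trials_per_activity):
                left = np.zeros((n_total, N_SENSORS), dtype=np.int64)
                right = np.zeros((n_total, N_SENSORS), dtype=np.int64)
                for k in range(config.steps_per_trial):
                    start = k * step_interval
                    target = left if k % 2 == 0 else right
                    target[start : start + stance_n] = levels_template
                rng = np.random.default_rng((noise_seed, trial_counter))
                left = _apply_level_noise(left, config.noise_level, rng)
                right = _apply_level_noise(right, config.noise_level, rng)
                trials.append(
                    PressureTrial(
                        trial_id=f"S{s + 1:02d}_A{int(activity)}_T{rep + 1:02d}",
                        subject_id=s + 1,
                        activity=activity,
                        left=left,
                        right=right,
                        rate_hz=config.rate_hz,
                    )
                )
                trial_counter += 1
    return trials
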