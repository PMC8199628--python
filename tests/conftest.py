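import numpy as np
import pytest

import tawagait as tg


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Study-sized noiseless cohort: 5 subjects x 3 activities x 6 trials."""
    cfg = tg.SimConfig(noise_level=0.0, seed=7)
    return tg.simulate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def small_cohort():
    """Quick cohort for protocol-level tests: 3 subjects x 3 trials."""
    cfg = tg.SimConfig(n_subjects=3, n_trials_per_activity=5, noise_level=0.1, seed=11)
    return tg.simulate_cohort(cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_trials(rng, n=3, max_len=30):
    """Small random-but-valid trials for round-trip and indexing tests."""
    trials = []
    for i in range(n):
        length = int(rng.integers(1, max_len))
        trials.append(
            tg.PressureTrial(
                trial_id=f"T{i}",
                subject_id=int(rng.integers(1, 5)),
                activity=tg.Activity(int(rng.integers(1, 4))),
                left=rng.integers(0, 4, (length, 8)),
                right=rng.integers(0, 4, (length, 8)),
            )
        )
    return trials
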