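"""TAWA feature family: hand values, closed forms, brute-force oracle,
weight-direction properties, normalization and window assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tawagait as tg
from tawagait.features import window_feature_names, windows_to_frame
from conftest import random_trials


def stance_from_rows(*rows):
    """Build an 8xT stance with the given per-sensor rows (rest zero)."""
    T = len(rows[0])
    s = np.zeros((8, T))
    for i, r in enumerate(rows):
        s[i] = r
    return s


def brute_force_features(stance):
    """Independent elementwise-loop oracle for all four operators."""
    n_sensors, T = stance.shape
    out = {"tiwa": [], "tdwa": [], "tidwa": [], "std": []}
    for i in range(n_sensors):
        inc = dec = flat = 0.0
        for k in range(1, T + 1):
            p = stance[i][k - 1]
            inc += p * k
            dec += p / k
            flat += p
        mean = flat / T
        var = sum((stance[i][k - 1] - mean) ** 2 for k in range(1, T + 1)) / T
        out["tiwa"].append(inc / T)
        out["tdwa"].append(dec / T)
        out["tidwa"].append(flat / T)
        out["std"].append(var**0.5)
    return {k: np.array(v) for k, v in out.items()}


class TestHandValues:
    """The worked example [0, 2, 3, 1] over T = 4."""

    stance = stance_from_rows([0, 2, 3, 1])

    def test_tiwa(self):
        assert tg.tiwa(self.stance)[0] == pytest.approx(4.25, abs=0)

    def test_tdwa(self):
        assert tg.tdwa(self.stance)[0] == pytest.approx(0.5625, abs=0)

    def test_tidwa(self):
        assert tg.tidwa(self.stance)[0] == pytest.approx(1.5, abs=0)

    def test_std_population_divisor(self):
        assert tg.stdfeat(self.stance)[0] == pytest.approx(np.sqrt(5 / 4), rel=1e-12)

    def test_two_point_std(self):
        assert tg.stdfeat(stance_from_rows([0, 3]))[0] == pytest.approx(1.5, abs=0)

    def test_all_zero_stance_gives_zero_features(self):
        s = np.zeros((8, 6))
        for op in (tg.tiwa, tg.tdwa, tg.tidwa, tg.stdfeat):
            assert (op(s) == 0).all()


class TestClosedForms:
    @pytest.mark.parametrize("T", range(1, 51))
    @pytest.mark.parametrize("c", [1, 3])
    def test_constant_stance(self, T, c):
        s = np.full((8, T), float(c))
        H_T = sum(1.0 / k for k in range(1, T + 1))
        np.testing.assert_allclose(tg.tiwa(s), c * (T + 1) / 2, rtol=1e-12)
        np.testing.assert_allclose(tg.tdwa(s), c * H_T / T, rtol=1e-12)
        np.testing.assert_allclose(tg.tidwa(s), c, rtol=1e-12)
        np.testing.assert_allclose(tg.stdfeat(s), 0, atol=0)

    def test_early_impulse_outweighs_late_in_tdwa(self):
        early = stance_from_rows([3, 0, 0])
        late = stance_from_rows([0, 0, 3])
        assert tg.tdwa(early)[0] == pytest.approx(1.0)
        assert tg.tdwa(late)[0] == pytest.approx(1 / 3)


class TestWeightDirection:
    @pytest.mark.parametrize("level", [1, 2, 3])
    @pytest.mark.parametrize("pos", range(9))
    def test_shifting_impulse_later(self, level, pos, T=10):
        a = np.zeros((8, T)); a[:, pos] = level
        b = np.zeros((8, T)); b[:, pos + 1] = level
        assert (tg.tiwa(b) > tg.tiwa(a)).all()
        assert (tg.tdwa(b) < tg.tdwa(a)).all()
        np.testing.assert_array_equal(tg.tidwa(b), tg.tidwa(a))

    def test_tidwa_time_permutation_invariant(self, rng):
        s = rng.integers(0, 4, (8, 12)).astype(float)
        perm = rng.permutation(12)
        np.testing.assert_allclose(tg.tidwa(s[:, perm]), tg.tidwa(s), rtol=1e-12)

    def test_weight_bounds(self, rng):
        for _ in range(50):
            s = rng.integers(0, 4, (8, int(rng.integers(1, 20)))).astype(float)
            assert (tg.tiwa(s) >= tg.tidwa(s) - 1e-12).all()
            assert (tg.tdwa(s) <= tg.tidwa(s) + 1e-12).all()

    def test_equality_when_all_mass_at_first_sample(self):
        s = np.zeros((8, 5)); s[:, 0] = 2
        np.testing.assert_allclose(tg.tiwa(s), tg.tidwa(s))
        np.testing.assert_allclose(tg.tdwa(s), tg.tidwa(s))


class TestBruteForceOracle:
    def test_thousand_random_stances(self, rng):
        for _ in range(1000):
            T = int(rng.integers(1, 30))
            s = rng.integers(0, 4, (8, T)).astype(float)
            oracle = brute_force_features(s)
            np.testing.assert_allclose(tg.tiwa(s), oracle["tiwa"], rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(tg.tdwa(s), oracle["tdwa"], rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(tg.tidwa(s), oracle["tidwa"], rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(tg.stdfeat(s), oracle["std"], rtol=1e-12, atol=1e-12)

    def test_tidwa_is_tiwa_with_unit_weights(self, rng):
        """Degenerate-weight equivalence via an explicit unit-weight loop."""
        s = rng.integers(0, 4, (8, 15)).astype(float)
        unit = np.array([sum(s[i]) / 15 for i in range(8)])
        np.testing.assert_allclose(tg.tidwa(s), unit, rtol=1e-12)


class TestEdgeCases:
    def test_empty_stance_rejected(self):
        with pytest.raises(ValueError, match="empty|T = 0"):
            tg.tiwa(np.zeros((8, 0)))

    def test_wrong_sensor_count_rejected(self):
        with pytest.raises(ValueError, match="8"):
            tg.tdwa(np.zeros((7, 4)))

    def test_delta_t_skips_warmup_samples(self):
        s = stance_from_rows([3, 0, 2, 1])
        # delta_t=2 drops k=1: tiwa = (0*2 + 2*3 + 1*4)/4
        assert tg.tiwa(s, delta_t=2)[0] == pytest.approx(10 / 4)
        assert tg.tidwa(s, delta_t=2)[0] == pytest.approx(3 / 4)

    def test_delta_t_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="delta_t"):
            tg.tiwa(np.zeros((8, 3)), delta_t=4)


class TestExtractStepFeatures:
    def test_one_record_per_segment_in_order(self, noiseless_cohort):
        trials, cfg = noiseless_cohort
        trial = trials[0]
        segs = tg.detect_steps(trial)
        feats = tg.extract_step_features(trial, segs)
        assert len(feats) == len(segs) == cfg.steps_per_trial
        assert [f.step_index for f in feats] == [s.step_index for s in segs]
        assert all(f.subject_id == trial.subject_id for f in feats)

    def test_matches_direct_computation(self, noiseless_cohort):
        trials, _ = noiseless_cohort
        trial = trials[3]
        seg = tg.detect_steps(trial)[2]
        f = tg.extract_step_features(trial, [seg])[0]
        stance = tg.slice_stance(trial, seg)
        np.testing.assert_allclose(f.tiwa, tg.tiwa(stance))
        np.testing.assert_allclose(f.std, tg.stdfeat(stance))

    def test_both_feet_mode_prefixes_stance_foot(self, noiseless_cohort):
        trials, _ = noiseless_cohort
        trial = trials[0]
        segs = tg.detect_steps(trial)[:3]
        stance_only = tg.extract_step_features(trial, segs)
        both = tg.extract_step_features(trial, segs, feet="both")
        for a, b in zip(stance_only, both):
            assert b.tiwa.size == 16
            np.testing.assert_array_equal(b.tiwa[:8], a.tiwa)
            np.testing.assert_array_equal(b.std[:8], a.std)
        windows = tg.make_windows(both, 2)
        assert windows[0].features.size == 64 * 2

    def test_segment_from_other_trial_rejected(self, noiseless_cohort):
        trials, _ = noiseless_cohort
        segs = tg.detect_steps(trials[0])
        with pytest.raises(ValueError, match="belongs to"):
            tg.extract_step_features(trials[1], segs)


class TestNormalize:
    def test_train_columns_standardized(self, rng):
        X = rng.normal(3, 5, (40, 6))
        Xn, _ = tg.normalize(X)
        np.testing.assert_allclose(Xn.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Xn.std(axis=0), 1, rtol=1e-12)

    def test_constant_column_passes_through_centred(self, rng):
        X = rng.normal(0, 1, (20, 3))
        X[:, 1] = 7.0
        Xn, scaler = tg.normalize(X)
        assert scaler.scale[1] == 1.0
        np.testing.assert_allclose(Xn[:, 1], 0, atol=1e-12)

    def test_heldout_rows_use_train_statistics(self, rng):
        train, test = rng.normal(0, 2, (30, 4)), rng.normal(1, 3, (10, 4))
        Xn, scaler = tg.normalize(train, apply_to=test)
        mu, sd = train.mean(axis=0), train.std(axis=0, ddof=0)
        np.testing.assert_allclose(Xn, (test - mu) / sd, rtol=1e-12)

    def test_agrees_with_sklearn_scaler(self, rng):
        from sklearn.preprocessing import StandardScaler

        train, test = rng.normal(0, 2, (30, 4)), rng.normal(1, 3, (10, 4))
        Xn, _ = tg.normalize(train, apply_to=test)
        ref = StandardScaler().fit(train).transform(test)
        np.testing.assert_allclose(Xn, ref, rtol=1e-10)

    def test_empty_train_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            tg.normalize(np.zeros((0, 4)))


class TestWindows:
    def _steps(self, trials):
        out = []
        for t in trials:
            out.extend(tg.extract_step_features(t, tg.detect_steps(t)))
        return out

    def test_window_count_is_s_minus_k_plus_1(self, noiseless_cohort):
        trials, cfg = noiseless_cohort
        steps = self._steps(trials[:6])
        s = cfg.steps_per_trial
        for k in range(1, s + 2):
            windows = tg.make_windows(steps, k)
            assert len(windows) == 6 * max(s - k + 1, 0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(s=st.integers(1, 15), k=st.integers(1, 20))
    def test_count_property_single_trial(self, s, k):
        steps = [
            tg.StepFeatures("t", i, 1, tg.Activity.LEVEL_WALK,
                            *(np.zeros(8),) * 4)
            for i in range(s)
        ]
        assert len(tg.make_windows(steps, k)) == max(s - k + 1, 0)

    def test_k1_windows_equal_step_blocks(self, noiseless_cohort):
        trials, _ = noiseless_cohort
        steps = self._steps(trials[:1])
        windows = tg.make_windows(steps, 1)
        assert len(windows) == len(steps)
        for w, sf in zip(windows, steps):
            np.testing.assert_array_equal(w.features, sf.block("tawa+std"))

    def test_windows_never_span_trials(self, noiseless_cohort):
        trials, cfg = noiseless_cohort
        steps = self._steps(trials[:4])
        for w in tg.make_windows(steps, 3):
            assert w.first_step_index + 3 <= cfg.steps_per_trial

    def test_feature_dimension_by_mode(self, noiseless_cohort):
        trials, _ = noiseless_cohort
        steps = self._steps(trials[:1])
        for k in (1, 4):
            assert tg.make_windows(steps, k, mode="tawa+std")[0].features.size == 32 * k
            assert tg.make_windows(steps, k, mode="tawa")[0].features.size == 24 * k

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            tg.make_windows([], 0)

    def test_frame_export_names_and_labels(self, noiseless_cohort):
        trials, _ = noiseless_cohort
        steps = self._steps(trials[:1])
        frame = windows_to_frame(tg.make_windows(steps, 1), mode="tawa+std")
        assert list(frame.columns[:4]) == ["activity", "subject_id", "trial_id", "first_step_index"]
        assert frame.columns[4] == "s1_tiwa"
        assert frame.shape[1] == 4 + 32
        names = window_feature_names(2, "tawa")
        assert names[0] == "step1_s1_tiwa" and len(names) == 48
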