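"""Candidate discovery, features, SVM classification and peak selection."""

import numpy as np
import pytest

from wristhr.errors import (InitializationError, ParameterError, StateError,
                            TrainingError)
from wristhr.tracking import (CandidatePeak, PeakClassifier, TrackerState,
                              featurize, find_candidates, initialize_state,
                              label_candidates, merge_channels, select_peak,
                              smoother_predict, to_bpm, train_classifier)

FS, N = 25.0, 1024


class TestFindCandidates:
    def test_single_peak_above_threshold(self):
        s = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        out = find_candidates(s, xi=0.7, fs=FS, n_grid=N)
        assert len(out) == 1
        assert out[0].bin == 2 and out[0].coe == 2.0

    def test_threshold_value(self):
        # kappa = 0.7 * max = 1.4: the 1.3 local maximum is excluded
        s = np.array([0.0, 1.3, 0.0, 2.0, 0.0])
        out = find_candidates(s, xi=0.7, fs=FS, n_grid=N)
        assert [c.bin for c in out] == [3]

    def test_plateau_yields_leftmost_bin(self):
        s = np.array([0.0, 2.0, 2.0, 0.0, 1.0])
        out = find_candidates(s, xi=0.7, fs=FS, n_grid=N)
        assert [c.bin for c in out] == [1]

    def test_boundary_maxima(self):
        s = np.array([3.0, 1.0, 0.0, 1.0, 2.9])
        out = find_candidates(s, xi=0.7, fs=FS, n_grid=N)
        assert [c.bin for c in out] == [0, 4]

    def test_all_zero_empty(self):
        assert find_candidates(np.zeros(10), 0.7, FS, N) == []


class TestMergeChannels:
    def c(self, b, coe, ch=0):
        return CandidatePeak(bin=b, freq_hz=b * FS / N, coe=coe, channel=ch)

    def test_disjoint_union(self):
        out = merge_channels([self.c(30, 1.0)], [self.c(40, 2.0, 1)])
        assert [x.bin for x in out] == [30, 40]

    def test_duplicate_keeps_larger(self):
        out = merge_channels([self.c(30, 5.0)], [self.c(30, 7.0, 1)])
        assert len(out) == 1 and out[0].coe == 7.0 and out[0].channel == 1

    def test_empty_plus_one(self):
        assert [x.bin for x in merge_channels([], [self.c(30, 1.0)])] == [30]


class TestFeaturize:
    def test_ratio_and_distance(self):
        cands = [CandidatePeak(bin=0, freq_hz=1.6, coe=5.0),
                 CandidatePeak(bin=1, freq_hz=1.2, coe=4.0)]
        out = featurize(cands, fprev=1.5)
        assert [c.C for c in out] == [1.0, 0.8]
        assert out[0].S == pytest.approx(0.1)

    def test_single_candidate_ratio_one(self):
        out = featurize([CandidatePeak(bin=0, freq_hz=1.0, coe=0.3)], 1.0)
        assert out[0].C == 1.0 and out[0].S == 0.0


class TestLabeling:
    def mk(self, bpms):
        return [CandidatePeak(bin=i, freq_hz=b / 60.0, coe=1.0)
                for i, b in enumerate(bpms)]

    def test_within_tolerance(self):
        out = label_candidates(self.mk([90.0]), true_bpm=90.5, tol_bpm=2.0)
        assert out[0].label == 1

    def test_single_true_with_tie_to_lower_bin(self):
        out = label_candidates(self.mk([89.0, 91.0]), true_bpm=90.0,
                               tol_bpm=2.0)
        assert [c.label for c in out] == [1, 0]

    def test_none_within_tolerance(self):
        out = label_candidates(self.mk([80.0, 100.0]), true_bpm=90.0,
                               tol_bpm=2.0)
        assert all(c.label == 0 for c in out)


def separable_set():
    rng = np.random.default_rng(0)
    true = np.column_stack([rng.uniform(0.8, 1.0, 20),
                            rng.uniform(0.0, 0.05, 20)])
    false = np.column_stack([rng.uniform(0.0, 0.3, 20),
                             rng.uniform(0.5, 1.0, 20)])
    feats = np.vstack([true, false])
    labels = np.array([1] * 20 + [0] * 20)
    return feats, labels


class TestClassifier:
    def test_separable_training_accuracy(self):
        feats, labels = separable_set()
        clf = train_classifier(feats, labels)
        assert (clf.predict(feats).astype(int) == labels).all()

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError, match="false-peak"):
            train_classifier(np.ones((5, 2)), np.ones(5, dtype=int))

    def test_duplicates_do_not_change_decision(self):
        # with a near-hard margin the separable solution is the max-margin
        # hyperplane, which duplication of consistent rows cannot move
        feats, labels = separable_set()
        clf1 = train_classifier(feats, labels, C=1e6)
        clf2 = train_classifier(np.vstack([feats, feats]),
                                np.concatenate([labels, labels]), C=1e6)
        grid = np.column_stack([np.linspace(0, 1, 25),
                                np.linspace(1, 0, 25)])
        np.testing.assert_allclose(clf1.decision_function(grid),
                                   clf2.decision_function(grid), atol=1e-6)

    def test_persistence_roundtrip(self, tmp_path):
        feats, labels = separable_set()
        clf = train_classifier(feats, labels)
        path = tmp_path / "clf.joblib"
        clf.save(path)
        loaded = PeakClassifier.load(path)
        grid = np.column_stack([np.linspace(0, 1, 25),
                                np.linspace(1, 0, 25)])
        np.testing.assert_array_equal(clf.predict(grid), loaded.predict(grid))

    def test_version_mismatch_refused(self, tmp_path):
        import joblib
        path = tmp_path / "bad.joblib"
        joblib.dump({"format": "wristhr-peak-classifier", "version": 99}, path)
        with pytest.raises(TrainingError, match="version"):
            PeakClassifier.load(path)


class TestSmoother:
    def test_perfect_line_extrapolated(self):
        hist = 1.4 + 0.01 * np.arange(10)
        assert smoother_predict(hist) == pytest.approx(hist[-1] + 0.01,
                                                       abs=1e-10)

    def test_constant_history(self):
        assert smoother_predict([1.5] * 10) == pytest.approx(1.5)

    def test_short_history_mean(self):
        assert smoother_predict([1.5]) == 1.5

    def test_empty_history_rejected(self):
        with pytest.raises(StateError):
            smoother_predict([])


class TestToBpm:
    def test_conversion(self):
        assert to_bpm(1.5) == 90.0
        assert to_bpm(0.0) == 0.0
        assert to_bpm(25.0 / 1024.0) == pytest.approx(1.46484375)

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            to_bpm(-0.1)


def _state(fprev, history, predictpre):
    st = TrackerState(smoother_window=10)
    st.fprev = fprev
    st.history.extend(history)
    st.predictpre = predictpre
    st.predict = predictpre
    st.initialized = True
    return st


class TestSelectPeak:
    def cands(self, freqs):
        return [CandidatePeak(bin=int(f * N / FS), freq_hz=f, coe=1.0)
                for f in freqs]

    def test_rule1_single_true(self):
        st = _state(1.5, [1.5] * 5, 1.5)
        f, flag = select_peak(self.cands([1.4, 1.6]),
                              np.array([False, True]), st)
        assert (f, flag) == (1.6, "rule1")
        assert st.fprev == 1.6

    def test_rule2_closest_to_previous(self):
        st = _state(1.45, [1.45] * 5, 1.45)
        f, flag = select_peak(self.cands([1.4, 1.6]),
                              np.array([True, True]), st)
        assert (f, flag) == (1.4, "rule2")

    def test_rule3_trend_up(self):
        hist = 1.41 + 0.01 * np.arange(10)   # predict = 1.51
        st = _state(1.50, hist, predictpre=1.49)
        f, flag = select_peak([], np.zeros(0, dtype=bool), st)
        assert flag == "predicted"
        assert f == 1.50 + 0.02
        assert f == pytest.approx(1.52, abs=1e-12)

    def test_rule3_trend_down(self):
        hist = 1.59 - 0.01 * np.arange(10)
        st = _state(1.50, hist, predictpre=1.51)
        f, flag = select_peak([], np.zeros(0, dtype=bool), st)
        assert f == 1.50 - 0.02

    def test_rule3_flat(self):
        st = _state(1.50, [1.5] * 10, predictpre=1.5)
        f, flag = select_peak([], np.zeros(0, dtype=bool), st)
        assert f == 1.50

    def test_rule3_step_is_exactly_one_grid_step(self):
        st = _state(1.50, [1.5] * 10, predictpre=1.4)
        f, _ = select_peak([], np.zeros(0, dtype=bool), st)
        assert abs(f - 1.50) == pytest.approx(0.02, abs=1e-15)

    def test_uninitialized_state_rejected(self):
        st = TrackerState()
        with pytest.raises(StateError):
            select_peak([], np.zeros(0, dtype=bool), st)


class TestInitialization:
    def test_picks_largest_in_band(self):
        cands = [CandidatePeak(bin=10, freq_hz=0.24, coe=9.0),   # below band
                 CandidatePeak(bin=60, freq_hz=1.46, coe=5.0),
                 CandidatePeak(bin=80, freq_hz=1.95, coe=4.0)]
        st = TrackerState()
        f, flag = initialize_state(cands, st, band_hz=(0.5, 3.0))
        assert f == 1.46 and flag == "initialized"
        assert st.initialized and st.fprev == 1.46

    def test_no_candidates_is_an_error(self):
        with pytest.raises(InitializationError):
            initialize_state([], TrackerState())
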