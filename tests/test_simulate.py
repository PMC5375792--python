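"""Synthetic treadmill-session generator."""

import numpy as np
import pytest

from wristhr import PipelineConfig, SimConfig, load_record, load_truth, \
    simulate_session, simulate_training_corpus
from wristhr.errors import ParameterError
from wristhr.io import preprocess, plan_windows, save_record, save_truth
from wristhr.simulate import hr_trace
from wristhr.spectrum import dft_dictionary, mfocuss


class TestDeterminism:
    def test_same_seed_identical(self, cfg):
        r1, t1 = simulate_session(SimConfig(seed=5, duration_s=30), cfg)
        r2, t2 = simulate_session(SimConfig(seed=5, duration_s=30), cfg)
        np.testing.assert_array_equal(r1.ppg, r2.ppg)
        np.testing.assert_array_equal(r1.accel, r2.accel)
        np.testing.assert_array_equal(t1, t2)

    def test_different_seed_differs(self, cfg):
        r1, _ = simulate_session(SimConfig(seed=5, duration_s=30), cfg)
        r2, _ = simulate_session(SimConfig(seed=6, duration_s=30), cfg)
        assert not np.array_equal(r1.ppg, r2.ppg)


class TestProtocol:
    def test_truth_within_protocol_bounds(self, cfg):
        _, truth = simulate_session(SimConfig(seed=0), cfg)
        assert truth.min() >= 60.0
        assert truth.max() <= 180.0

    def test_truth_one_value_per_window(self, cfg):
        record, truth = simulate_session(SimConfig(seed=1, duration_s=60), cfg)
        ppg, _ = preprocess(record, cfg)
        plan = plan_windows(ppg.shape[1], cfg)
        assert len(truth) == plan.n_windows

    def test_out_of_range_protocol_rejected(self):
        with pytest.raises(ParameterError):
            SimConfig(hr_protocol=((30.0, 80.0, 260.0),))

    def test_hr_trace_is_piecewise_linear(self):
        cfg = SimConfig(seed=0, duration_s=90,
                        hr_protocol=((30.0, 80.0, 80.0), (60.0, 80.0, 140.0)))
        hr = hr_trace(cfg)
        assert hr[0] == 80.0
        assert hr[int(29 * 125)] == pytest.approx(80.0, abs=0.1)
        assert hr[-1] == pytest.approx(140.0, abs=0.1)


class TestSpectralGroundTruth:
    def test_cardiac_line_dominates_noise_free_windows(self, cfg):
        sim = SimConfig(seed=3, duration_s=40, artifact_gain=(0.0, 0.0),
                        ppg_noise_sd=0.0, accel_noise_sd=0.0)
        record, truth = simulate_session(sim, cfg)
        ppg, _ = preprocess(record, cfg)
        plan = plan_windows(ppg.shape[1], cfg)
        dic = dft_dictionary(plan.window_samples, cfg.n_grid)
        for wi in (0, len(plan.slices) // 2, len(plan.slices) - 1):
            s, e = plan.slices[wi]
            frame = mfocuss(ppg[:, s:e].T, dic)
            top = int(np.argmax(frame.S[:cfg.max_bin + 1, 0]))
            hr_bin = truth[wi] / 60.0 * cfg.n_grid / cfg.fs_target
            assert abs(top - hr_bin) <= 1.0

    def test_artifact_aligns_with_accel_spectrum(self, cfg):
        # strong artifact, weak cardiac content: the dominant PPG bin must
        # coincide with the dominant accelerometer bin
        sim = SimConfig(seed=4, duration_s=40, artifact_gain=(3.0, 3.0),
                        harmonic_amps=(0.05, 0.0, 0.0), ppg_noise_sd=0.0,
                        accel_noise_sd=0.0)
        record, _ = simulate_session(sim, cfg)
        ppg, accel = preprocess(record, cfg)
        plan = plan_windows(ppg.shape[1], cfg)
        dic = dft_dictionary(plan.window_samples, cfg.n_grid)
        s, e = plan.slices[len(plan.slices) // 2]
        f_ppg = mfocuss(ppg[:, s:e].T, dic)
        f_acc = mfocuss(accel[:, s:e].T, dic)
        b = cfg.max_bin + 1
        top_ppg = int(np.argmax(f_ppg.S[:b].sum(axis=1)))
        top_acc = int(np.argmax(f_acc.S[:b].sum(axis=1)))
        assert abs(top_ppg - top_acc) <= 1

    def test_cadence_stays_clear_of_heart_rate(self):
        from wristhr.simulate import _cadence_trace
        cfg = SimConfig(seed=5)
        rng = np.random.default_rng(5)
        n = int(cfg.duration_s * cfg.fs)
        t = np.arange(n) / cfg.fs
        f_hr = hr_trace(cfg) / 60.0
        cad = _cadence_trace(cfg, f_hr, t, rng)
        assert np.min(np.abs(cad - f_hr)) >= 0.3


class TestFileRoundTrip:
    def test_mat_and_csv_roundtrip(self, cfg, tmp_path):
        record, truth = simulate_session(SimConfig(seed=6, duration_s=20), cfg)
        for fmt in ("mat", "csv"):
            path = tmp_path / f"sess.{fmt}"
            save_record(record, path, fmt=fmt)
            loaded = load_record(path)
            np.testing.assert_allclose(loaded.ppg, record.ppg)
            np.testing.assert_allclose(loaded.accel, record.accel)
        tpath = tmp_path / "sess_bpm.txt"
        save_truth(truth, tpath)
        np.testing.assert_allclose(load_truth(tpath), truth)


class TestTrainingCorpus:
    def test_both_classes_with_plausible_balance(self, corpus):
        feats, labels = corpus
        n1 = labels.sum()
        n0 = len(labels) - n1
        assert n1 > 0 and n0 > 0
        ratio = n1 / n0
        assert 1 / 20 <= ratio <= 4.0
        assert feats.shape == (len(labels), 2)
        assert np.all(feats[:, 0] <= 1.0 + 1e-12)
        assert np.all(feats[:, 1] >= 0.0)

    def test_zero_sessions_rejected(self):
        with pytest.raises(ParameterError):
            simulate_training_corpus(n_sessions=0)
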