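"""Session-level heart-rate estimation: the Model / Results objects.

:class:`HeartRateModel` wraps one :class:`~wristhr.io.SensorRecord` with a
configuration and a trained peak classifier; :meth:`HeartRateModel.fit` runs
the full per-window pipeline (preprocess -> PCA motion reference -> LMS ->
MMV sparse spectra -> spectrum subtraction -> candidate classification ->
selection) and returns a :class:`HeartRateResults` carrying the per-window
BPM trace, provenance flags and diagnostics.

``estimate_session`` and ``run_training`` are thin functional entry points
over these objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import io as wio
from .config import PipelineConfig
from .errors import ParameterError, PipelineError, TrainingError
from .lms import lms_denoise
from .metrics import EvalReport, cross_validate, evaluate_trace
from .motion import first_pc_reference
from .spectrum import MFOCUSSConfig, dft_dictionary, mfocuss
from .subtraction import clean_spectra
from .tracking import (CandidatePeak, PeakClassifier, TrackerState,
                       featurize, find_candidates, initialize_state,
                       label_candidates, merge_channels, select_peak,
                       to_bpm, train_classifier)

log = logging.getLogger(__name__)


@dataclass
class WindowFrame:
    """Per-window intermediate products handed to the tracker."""

    index: int
    start: int
    end: int
    candidates: list            # merged CandidatePeak list
    explained_ratio: float
    residual_ppg: float
    residual_acc: float
    converged: bool


def _mf_config(cfg: PipelineConfig) -> MFOCUSSConfig:
    return MFOCUSSConfig(lam=cfg.lam, p=cfg.p, max_iter=cfg.mf_max_iter,
                         tol=cfg.mf_tol, prune_thresh=cfg.mf_prune)


def iter_window_frames(record: wio.SensorRecord,
                       cfg: PipelineConfig) -> Iterator[WindowFrame]:
    """Run the signal chain window by window, yielding merged candidates.

    LMS tap weights carry over between successive windows of the session;
    the PCA motion reference is recomputed per window.
    """
    try:
        ppg, accel = wio.preprocess(record, cfg)
    except Exception as exc:
        raise PipelineError(-1, "preprocess", exc) from exc
    plan = wio.plan_windows(ppg.shape[1], cfg)
    dic = dft_dictionary(plan.window_samples, cfg.n_grid)
    mfcfg = _mf_config(cfg)
    carry = [None, None]
    for wi, (s, e) in enumerate(plan.slices):
        stage = "motion_reference"
        try:
            a, pca = first_pc_reference(accel[:, s:e])
            stage = "lms_filter"
            cleansed = []
            for ch in range(2):
                ech, lstate = lms_denoise(ppg[ch, s:e], a, cfg.lms_order,
                                          cfg.mu, w0=carry[ch])
                carry[ch] = lstate.weights
                cleansed.append(ech)
            stage = "sparse_spectrum"
            frame_ppg = mfocuss(np.column_stack(cleansed), dic, mfcfg)
            frame_acc = mfocuss(accel[:, s:e].T, dic, mfcfg)
            stage = "spectrum_subtraction"
            cs = clean_spectra(frame_ppg.S, frame_acc.S, cfg.max_bin,
                               cfg.subtract_fraction)
            stage = "peak_discovery"
            c1 = find_candidates(cs.s1, cfg.xi, cfg.fs_target, cfg.n_grid, 0)
            c2 = find_candidates(cs.s2, cfg.xi, cfg.fs_target, cfg.n_grid, 1)
            merged = merge_channels(c1, c2)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(wi, stage, exc) from exc
        yield WindowFrame(
            index=wi, start=s, end=e, candidates=merged,
            explained_ratio=pca.explained_ratio,
            residual_ppg=frame_ppg.residual,
            residual_acc=frame_acc.residual,
            converged=frame_ppg.converged and frame_acc.converged,
        )


class HeartRateModel:
    """Heart-rate estimator for one session.

    Parameters
    ----------
    record : SensorRecord
        The loaded session (2 PPG + 3 accelerometer channels).
    classifier : PeakClassifier
        A trained true/false peak classifier.
    config : PipelineConfig, optional
        Pipeline parameters; defaults to the standard operating point.
    """

    def __init__(self, record: wio.SensorRecord, classifier: PeakClassifier,
                 config: Optional[PipelineConfig] = None):
        self.record = record
        self.classifier = classifier
        self.config = config or PipelineConfig()

    @classmethod
    def from_file(cls, path, classifier, config=None, truth_path=None,
                  fmt=None) -> "HeartRateModel":
        record = wio.load_record(path, fmt=fmt, truth_path=truth_path)
        return cls(record, classifier, config)

    def fit(self) -> "HeartRateResults":
        cfg = self.config
        state = TrackerState(smoother_window=cfg.smoother_window)
        rows = []
        diagnostics = []
        truth = self.record.truth_bpm
        for frame in iter_window_frames(self.record, cfg):
            try:
                if not state.initialized:
                    f_hr, flag = initialize_state(frame.candidates, state,
                                                  cfg.init_band_hz)
                else:
                    cands = featurize(frame.candidates, state.fprev)
                    if cands:
                        feats = np.array([[c.C, c.S] for c in cands])
                        preds = self.classifier.predict(feats)
                    else:
                        preds = np.zeros(0, dtype=bool)
                    f_hr, flag = select_peak(cands, preds, state,
                                             cfg.pred_step_hz,
                                             cfg.bpm_min, cfg.bpm_max)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(frame.index, "peak_tracking", exc) from exc
            rows.append({
                "window_index": frame.index,
                "window_start_s": frame.start / cfg.fs_target,
                "bpm_est": to_bpm(f_hr),
                "bpm_true": (float(truth[frame.index])
                             if truth is not None and frame.index < len(truth)
                             else np.nan),
                "flag": flag,
            })
            diagnostics.append({
                "window_index": frame.index,
                "n_candidates": len(frame.candidates),
                "explained_ratio": frame.explained_ratio,
                "residual_ppg": frame.residual_ppg,
                "residual_acc": frame.residual_acc,
                "converged": frame.converged,
            })
        trace = pd.DataFrame(rows)
        diag = pd.DataFrame(diagnostics)
        return HeartRateResults(self, trace, diag)


class HeartRateResults:
    """Fitted per-window heart-rate trace with provenance and diagnostics."""

    def __init__(self, model: HeartRateModel, trace: pd.DataFrame,
                 diagnostics: pd.DataFrame):
        self.model = model
        self.trace = trace
        self.diagnostics = diagnostics

    @property
    def bpm_est(self) -> np.ndarray:
        return self.trace["bpm_est"].to_numpy()

    @property
    def bpm_true(self) -> np.ndarray:
        return self.trace["bpm_true"].to_numpy()

    @property
    def n_windows(self) -> int:
        return len(self.trace)

    def evaluate(self, truth=None, cv_accuracy=None) -> EvalReport:
        """Score the trace against ground truth (window-aligned BPM)."""
        if truth is None:
            truth = self.bpm_true
            if np.isnan(truth).any():
                raise ParameterError("no ground truth attached to this session")
        return evaluate_trace(self.bpm_est, truth, cv_accuracy=cv_accuracy)

    def to_csv(self, path) -> None:
        self.trace.to_csv(path, index=False, float_format="%.6f")

    def summary(self) -> str:
        est = self.bpm_est
        flags = self.trace["flag"].value_counts().to_dict()
        lines = [
            "HeartRateModel results",
            "======================",
            f"windows              {self.n_windows}",
            f"window / hop         {self.model.config.window_s:g} s / "
            f"{self.model.config.shift_s:g} s",
            f"BPM mean (range)     {est.mean():.1f} "
            f"({est.min():.1f}-{est.max():.1f})",
            "selection flags      "
            + ", ".join(f"{k}={v}" for k, v in sorted(flags.items())),
        ]
        if not np.isnan(self.bpm_true).any():
            rep = self.evaluate()
            lines += [
                f"AAE                  {rep.aae:.3f} BPM",
                f"AAEP                 {rep.aaep:.3f} %",
                f"Pearson r            {rep.pearson_r:.4f}",
                f"Bland-Altman LOA     [{rep.loa[0]:.2f}, {rep.loa[1]:.2f}] BPM",
            ]
        return "\n".join(lines)

    def plot_trace(self, path=None):
        """Estimated (and true, if present) BPM against window start time."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 4))
        t = self.trace["window_start_s"]
        ax.plot(t, self.bpm_est, label="estimate")
        if not np.isnan(self.bpm_true).any():
            ax.plot(t, self.bpm_true, "--", label="ground truth")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("heart rate (BPM)")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def extract_labeled_features(record: wio.SensorRecord, cfg: PipelineConfig,
                             truth: Optional[np.ndarray] = None):
    """Pooled labeled (C, S) features from one session with ground truth.

    During training the previous-window *truth* frequency plays the role of
    the previous accepted estimate when computing the distance feature S.
    Returns ``(features (n, 2), labels (n,))``.
    """
    if truth is None:
        truth = record.truth_bpm
    if truth is None:
        raise TrainingError(
            f"session {record.subject_id!r} has no ground-truth BPM"
        )
    truth = np.asarray(truth, dtype=float).ravel()
    feats, labs = [], []
    for frame in iter_window_frames(record, cfg):
        if frame.index >= len(truth):
            break
        fprev_true = truth[frame.index - 1] / 60.0 if frame.index > 0 \
            else truth[frame.index] / 60.0
        cands = featurize(frame.candidates, fprev_true)
        cands = label_candidates(cands, truth[frame.index], cfg.label_tol_bpm)
        for c in cands:
            feats.append([c.C, c.S])
            labs.append(c.label)
    if not feats:
        return np.zeros((0, 2)), np.zeros(0, dtype=int)
    return np.asarray(feats, dtype=float), np.asarray(labs, dtype=int)


def estimate_session(record: wio.SensorRecord, cfg: PipelineConfig,
                     classifier: PeakClassifier) -> HeartRateResults:
    """Functional entry point: fit a HeartRateModel on one session."""
    return HeartRateModel(record, classifier, cfg).fit()


def run_training(records, cfg: Optional[PipelineConfig] = None,
                 truths=None, cv_folds: int = 10):
    """Train the peak classifier on sessions with ground truth.

    ``records`` is a sequence of SensorRecord; ``truths`` optionally
    overrides the truth attached to each record.  Returns
    ``(PeakClassifier, cv_accuracy_percent)``; cross-validation accuracy is
    None when a class is too small to stratify.
    """
    cfg = cfg or PipelineConfig()
    if truths is None:
        truths = [None] * len(records)
    missing = [r.subject_id for r, t in zip(records, truths)
               if t is None and r.truth_bpm is None]
    if missing:
        raise TrainingError(f"sessions missing ground truth: {missing}")
    feats, labs = [], []
    for record, truth in zip(records, truths):
        f, l = extract_labeled_features(record, cfg, truth)
        if len(l) == 0:
            log.warning("session %r yielded no candidates; skipped",
                        record.subject_id)
            continue
        feats.append(f)
        labs.append(l)
    if not feats:
        raise TrainingError("no labeled candidates found in any session")
    features = np.vstack(feats)
    labels = np.concatenate(labs)
    clf = train_classifier(features, labels, kernel=cfg.svm_kernel)
    try:
        cv_acc = cross_validate(features, labels, k=cv_folds, seed=cfg.seed,
                                kernel=cfg.svm_kernel)
    except ParameterError:
        cv_acc = None
    return clf, cv_acc
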