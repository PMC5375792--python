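"""Spectral peak discovery, SVM classification and heart-rate tracking.

Peak tracking is cast as binary classification of candidate spectral peaks.
Candidates are local maxima of the cleansed PPG spectra above the adaptive
threshold kappa = xi * max(spectrum).  Two features describe each candidate:

* ``C`` — its coefficient divided by the largest candidate coefficient in
  the window (the true cardiac peak usually dominates);
* ``S`` — the absolute distance in Hz from the previous accepted frequency
  (heart rate moves slowly between overlapping windows).

A linear-kernel SVM over min-max-scaled (C, S) separates true from false
peaks.  Selection rules: a single predicted-true candidate wins outright;
among several, the one closest to the previous estimate wins; if none is
predicted true the estimate is nudged by 0.02 Hz in the direction of the
recent trend, extrapolated by an ordinary least-squares line over the last
ten accepted frequencies.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .errors import (InitializationError, ParameterError, StateError,
                     TrainingError)

log = logging.getLogger(__name__)

MODEL_FORMAT = "wristhr-peak-classifier"
MODEL_VERSION = 1


@dataclass
class CandidatePeak:
    bin: int
    freq_hz: float
    coe: float                       # peak coefficient
    channel: int = 0                 # origin PPG channel (0 or 1)
    C: Optional[float] = None        # coefficient ratio coe / coe_max
    S: Optional[float] = None        # |freq - fprev| in Hz
    label: Optional[int] = None      # 1 true peak, 0 false peak (training)


@dataclass
class TrackerState:
    """Carries the previous estimate and the smoother bookkeeping."""

    smoother_window: int = 10
    fprev: float = 0.0
    history: deque = field(default_factory=deque)
    predict: float = 0.0
    predictpre: float = 0.0
    initialized: bool = False

    def __post_init__(self):
        self.history = deque(self.history, maxlen=self.smoother_window)


def find_candidates(s: np.ndarray, xi: float, fs: float, n_grid: int,
                    channel: int = 0) -> list[CandidatePeak]:
    """Local maxima of a cleansed spectrum above kappa = xi * max(s).

    Maxima are strict against their neighbors; boundary bins compare to
    their single neighbor; a plateau (run of equal values higher than both
    sides) contributes one candidate at its leftmost bin.
    """
    s = np.asarray(s, dtype=float)
    if not s.any():
        return []
    kappa = xi * s.max()
    out = []
    i = 0
    n = len(s)
    while i < n:
        j = i
        while j + 1 < n and s[j + 1] == s[i]:
            j += 1
        left_ok = i == 0 or s[i - 1] < s[i]
        right_ok = j == n - 1 or s[j + 1] < s[i]
        if left_ok and right_ok and s[i] > kappa and s[i] > 0:
            out.append(CandidatePeak(bin=i, freq_hz=i * fs / n_grid,
                                     coe=float(s[i]), channel=channel))
        i = j + 1
    return out


def merge_channels(c1: Sequence[CandidatePeak],
                   c2: Sequence[CandidatePeak]) -> list[CandidatePeak]:
    """Union of the two channels' candidates by bin; larger coefficient wins."""
    by_bin: dict[int, CandidatePeak] = {}
    for cand in list(c1) + list(c2):
        cur = by_bin.get(cand.bin)
        if cur is None or cand.coe > cur.coe:
            by_bin[cand.bin] = cand
    return [by_bin[b] for b in sorted(by_bin)]


def featurize(cands: Sequence[CandidatePeak], fprev: float) -> list[CandidatePeak]:
    """Fill C (ratio to the merged-set maximum) and S (|f - fprev|, Hz)."""
    if not cands:
        return []
    coe_max = max(c.coe for c in cands)
    for c in cands:
        c.C = c.coe / coe_max
        c.S = abs(c.freq_hz - fprev)
    return list(cands)


def label_candidates(cands: Sequence[CandidatePeak], true_bpm: float,
                     tol_bpm: float = 2.0) -> list[CandidatePeak]:
    """Label the candidate nearest the truth (within tolerance) as the true peak.

    At most one candidate per window is labeled 1; ties go to the lower bin.
    """
    cands = list(cands)
    for c in cands:
        c.label = 0
    eligible = [(abs(c.freq_hz * 60.0 - true_bpm), c.bin, c) for c in cands
                if abs(c.freq_hz * 60.0 - true_bpm) <= tol_bpm]
    if eligible:
        eligible.sort(key=lambda t: (t[0], t[1]))
        eligible[0][2].label = 1
    return cands


class PeakClassifier:
    """SVM over (C, S) features, with min-max scaling fitted on training data."""

    def __init__(self, kernel: str = "linear", C: float = 1.0):
        self.kernel = kernel
        self.C = C
        self._pipe = Pipeline([
            ("scale", MinMaxScaler()),
            ("svc", SVC(kernel=kernel, C=C, class_weight="balanced")),
        ])
        self.meta: dict = {}

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "PeakClassifier":
        features = np.asarray(features, dtype=float)
        labels = np.asarray(labels, dtype=int).ravel()
        if features.ndim != 2 or features.shape[1] != 2:
            raise ParameterError("features must be an (n, 2) array of (C, S)")
        present = set(np.unique(labels).tolist())
        for cls_ in (0, 1):
            if cls_ not in present:
                name = "false-peak (0)" if cls_ == 0 else "true-peak (1)"
                raise TrainingError(f"training set has no {name} examples")
        self._pipe.fit(features, labels)
        self.meta = {
            "n_samples": int(len(labels)),
            "n_true": int(labels.sum()),
            "n_false": int(len(labels) - labels.sum()),
            "kernel": self.kernel,
        }
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.size == 0:
            return np.zeros(0, dtype=bool)
        return self._pipe.predict(features).astype(bool)

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        return self._pipe.decision_function(np.asarray(features, dtype=float))

    def save(self, path) -> None:
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "kernel": self.kernel,
            "C": self.C,
            "pipeline": self._pipe,
            "meta": self.meta,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path) -> "PeakClassifier":
        path = Path(path)
        if not path.exists():
            raise TrainingError(f"no such model file: {path}")
        payload = joblib.load(path)
        if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
            raise TrainingError(f"{path}: not a peak-classifier artifact")
        if payload.get("version") != MODEL_VERSION:
            raise TrainingError(
                f"{path}: model version {payload.get('version')} is not "
                f"supported (expected {MODEL_VERSION})"
            )
        obj = cls(kernel=payload["kernel"], C=payload["C"])
        obj._pipe = payload["pipeline"]
        obj.meta = payload.get("meta", {})
        return obj


def train_classifier(features: np.ndarray, labels: np.ndarray,
                     kernel: str = "linear", C: float = 1.0) -> PeakClassifier:
    """Train the peak classifier; both classes must be present."""
    return PeakClassifier(kernel=kernel, C=C).fit(features, labels)


def smoother_predict(history: Sequence[float]) -> float:
    """Trend extrapolation over the recent accepted frequencies.

    With three or more points, fits an ordinary least-squares line over
    (index, frequency) and evaluates it one step ahead; with fewer, returns
    the mean.
    """
    hist = np.asarray(list(history), dtype=float)
    if hist.size == 0:
        raise StateError("smoother requires a nonempty history")
    if hist.size < 3:
        return float(hist.mean())
    idx = np.arange(hist.size, dtype=float)
    slope, intercept = np.polyfit(idx, hist, 1)
    return float(slope * hist.size + intercept)


def to_bpm(f_hr: float) -> float:
    """BPM = frequency in Hz x 60."""
    if f_hr < 0:
        raise ParameterError(f"frequency must be nonnegative, got {f_hr}")
    return f_hr * 60.0


def initialize_state(cands: Sequence[CandidatePeak], state: TrackerState,
                     band_hz: tuple = (0.5, 3.0)) -> tuple[float, str]:
    """First-window initialization: largest candidate in the plausible HR band.

    Falls back to the largest candidate overall if none lies in the band;
    raises if the first window produced no candidates at all.
    """
    cands = list(cands)
    if not cands:
        raise InitializationError("no spectral candidates in the first window")
    in_band = [c for c in cands if band_hz[0] <= c.freq_hz <= band_hz[1]]
    pool = in_band if in_band else cands
    best = max(pool, key=lambda c: c.coe)
    f0 = best.freq_hz
    state.fprev = f0
    state.history.append(f0)
    state.predict = f0
    state.predictpre = f0
    state.initialized = True
    return f0, "initialized"


def select_peak(cands: Sequence[CandidatePeak], predictions: np.ndarray,
                state: TrackerState, pred_step_hz: float = 0.02,
                bpm_min: float = 30.0, bpm_max: float = 230.0) -> tuple[float, str]:
    """Apply the selection rules and update the tracker state.

    Rule 1: exactly one predicted-true candidate -> its frequency.
    Rule 2: several -> the one closest to fprev (tie -> lower frequency).
    Rule 3: none -> fprev nudged by ``pred_step_hz`` in the direction of the
    smoother trend h = predict - predictpre (no change when h = 0).

    Returns ``(f_hr, flag)`` with flag in {rule1, rule2, predicted}.
    """
    if not state.initialized:
        raise StateError("select_peak requires an initialized tracker state")
    cands = list(cands)
    predictions = np.asarray(predictions, dtype=bool)
    if len(predictions) != len(cands):
        raise ParameterError("predictions and candidates differ in length")

    predict = smoother_predict(state.history)
    h = predict - state.predictpre
    if abs(h) < 1e-12:   # numerically flat trend counts as no trend
        h = 0.0

    true_set = [c for c, p in zip(cands, predictions) if p]
    if len(true_set) == 1:
        f_hr, flag = true_set[0].freq_hz, "rule1"
    elif len(true_set) > 1:
        best = min(true_set, key=lambda c: (abs(c.freq_hz - state.fprev),
                                            c.freq_hz))
        f_hr, flag = best.freq_hz, "rule2"
    else:
        if h > 0:
            f_hr = state.fprev + pred_step_hz
        elif h < 0:
            f_hr = state.fprev - pred_step_hz
        else:
            f_hr = state.fprev
        flag = "predicted"

    lo, hi = bpm_min / 60.0, bpm_max / 60.0
    if not (lo <= f_hr <= hi):
        log.warning("estimate %.3f Hz outside [%g, %g] BPM; clamped",
                    f_hr, bpm_min, bpm_max)
        f_hr = min(max(f_hr, lo), hi)

    state.fprev = f_hr
    state.history.append(f_hr)
    state.predictpre = predict
    state.predict = predict
    return f_hr, flag
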