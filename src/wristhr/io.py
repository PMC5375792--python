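"""Reading, writing and preprocessing of multi-channel wrist recordings.

A session is a 6-row matrix at 125 Hz in the on-disk dialects
(ECG, PPG1, PPG2, ACCX, ACCY, ACCZ); in memory we keep only the two PPG and
three accelerometer channels in a :class:`SensorRecord`.  Preprocessing
decimates to 25 Hz, band-passes 0.4-4 Hz with a zero-phase second-order
Butterworth filter and slices the stream into 8-s windows with 2-s hops.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.signal

from .config import PipelineConfig
from .errors import DataError, FormatError, ParameterError, TooShortError

_CSV_COLUMNS = ["ppg1", "ppg2", "accx", "accy", "accz"]


@dataclass
class SensorRecord:
    """One recording session: 2 PPG + 3 accelerometer channels."""

    ppg: np.ndarray              # (2, T)
    accel: np.ndarray            # (3, T)
    fs: float                    # Hz
    truth_bpm: Optional[np.ndarray] = None   # one value per analysis window
    subject_id: str = ""

    def __post_init__(self):
        self.ppg = np.atleast_2d(np.asarray(self.ppg, dtype=float))
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        if self.ppg.shape[0] != 2 or self.accel.shape[0] != 3:
            raise FormatError(
                f"expected 2 PPG and 3 accel channels, got {self.ppg.shape[0]} "
                f"and {self.accel.shape[0]}"
            )
        if self.ppg.shape[1] != self.accel.shape[1]:
            raise FormatError("PPG and accel channels differ in length")
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.truth_bpm is not None:
            self.truth_bpm = np.asarray(self.truth_bpm, dtype=float).ravel()

    @property
    def n_samples(self) -> int:
        return self.ppg.shape[1]


@dataclass
class WindowPlan:
    """Sliding-window layout: half-open, 0-based sample ranges."""

    window_s: float
    shift_s: float
    fs_target: float
    slices: list  # list[(start, end)]

    @property
    def window_samples(self) -> int:
        return int(round(self.window_s * self.fs_target))

    @property
    def n_windows(self) -> int:
        return len(self.slices)

    def start_times(self) -> np.ndarray:
        return np.array([s for s, _ in self.slices]) / self.fs_target


def _check_finite(arr: np.ndarray, what: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise DataError(f"{what} contains non-finite value at index {tuple(idx)}")


def load_record(path, fmt: Optional[str] = None, fs: float = 125.0,
                truth_path=None, subject_id: Optional[str] = None) -> SensorRecord:
    """Load a session from a MATLAB v5 ``.mat`` file or the CSV dialect.

    The ``.mat`` file must hold one 6 x T matrix with row order
    ECG, PPG1, PPG2, ACCX, ACCY, ACCZ; the ECG row is discarded (ground truth
    is consumed from a companion BPM file, never derived here).  The CSV
    dialect has a header naming the channels and an optional ``# fs=125``
    comment line.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt is None:
        fmt = "mat" if path.suffix.lower() == ".mat" else "csv"
    if fmt == "mat":
        sig = _load_mat_matrix(path)
        ppg, accel = sig[1:3], sig[3:6]
    elif fmt == "csv":
        ppg, accel, fs = _load_csv(path, fs)
    else:
        raise ParameterError(f"unknown format {fmt!r} (expected 'mat' or 'csv')")
    _check_finite(ppg, "PPG")
    _check_finite(accel, "acceleration")
    truth = load_truth(truth_path) if truth_path is not None else None
    return SensorRecord(ppg=ppg, accel=accel, fs=fs, truth_bpm=truth,
                        subject_id=subject_id or path.stem)


def _load_mat_matrix(path) -> np.ndarray:
    mat = scipy.io.loadmat(path)
    arrays = [(k, v) for k, v in mat.items()
              if not k.startswith("__") and isinstance(v, np.ndarray)
              and v.ndim == 2 and min(v.shape) >= 2]
    if not arrays:
        raise FormatError(f"{path}: no 2-D signal matrix found")
    # prefer the conventional 'sig' variable, else the largest matrix
    arrays.sort(key=lambda kv: (kv[0] != "sig", -kv[1].size))
    name, sig = arrays[0]
    if sig.shape[0] != 6 and sig.shape[1] == 6:
        sig = sig.T
    if sig.shape[0] != 6:
        raise FormatError(
            f"{path}: variable {name!r} has {sig.shape[0]} rows, expected 6 "
            "(ECG, PPG1, PPG2, ACCX, ACCY, ACCZ)"
        )
    return np.asarray(sig, dtype=float)


def _load_csv(path, fs_default: float):
    fs = fs_default
    body = []
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("#"):
                if "fs=" in stripped:
                    try:
                        fs = float(stripped.split("fs=")[1].split()[0])
                    except ValueError as exc:
                        raise FormatError(f"{path}: bad fs comment {stripped!r}") from exc
                continue
            if stripped:
                body.append(line)
    if not body:
        raise FormatError(f"{path}: empty CSV")
    df = pd.read_csv(_stdio.StringIO("".join(body)),
                     float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    ppg = df[["ppg1", "ppg2"]].to_numpy(dtype=float).T
    accel = df[["accx", "accy", "accz"]].to_numpy(dtype=float).T
    return ppg, accel, fs


def load_truth(path) -> np.ndarray:
    """Load the companion per-window ground-truth BPM vector."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such truth file: {path}")
    if path.suffix.lower() == ".mat":
        mat = scipy.io.loadmat(path)
        vecs = [v for k, v in mat.items()
                if not k.startswith("__") and isinstance(v, np.ndarray)
                and v.size == max(v.shape)]
        if not vecs:
            raise FormatError(f"{path}: no BPM vector found")
        truth = np.asarray(vecs[0], dtype=float).ravel()
    else:
        truth = np.loadtxt(path, dtype=float, comments="#").ravel()
    _check_finite(truth, "truth BPM")
    return truth


def save_record(record: SensorRecord, path, fmt: Optional[str] = None,
                ecg: Optional[np.ndarray] = None) -> None:
    """Write a record in the 6-row ``.mat`` dialect or the CSV dialect."""
    path = Path(path)
    if fmt is None:
        fmt = "mat" if path.suffix.lower() == ".mat" else "csv"
    if fmt == "mat":
        row0 = np.zeros(record.n_samples) if ecg is None else np.asarray(ecg, float)
        sig = np.vstack([row0, record.ppg, record.accel])
        scipy.io.savemat(path, {"sig": sig})
    elif fmt == "csv":
        cols = {"ppg1": record.ppg[0], "ppg2": record.ppg[1],
                "accx": record.accel[0], "accy": record.accel[1],
                "accz": record.accel[2]}
        if ecg is not None:
            cols["ecg"] = np.asarray(ecg, float)
        df = pd.DataFrame(cols)
        with open(path, "w") as fh:
            fh.write(f"# fs={record.fs:g}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
    else:
        raise ParameterError(f"unknown format {fmt!r}")


def save_truth(truth_bpm: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(truth_bpm, float), fmt="%.17g")


def downsample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Anti-alias low-pass and decimate by the integer factor fs_in/fs_out."""
    factor = fs_in / fs_out
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ParameterError(
            f"unsupported rate conversion {fs_in} -> {fs_out} Hz "
            "(factor must be a positive integer)"
        )
    q = int(round(factor))
    x = np.asarray(x, dtype=float)
    if q == 1:
        return x.copy()
    x = x[: (len(x) // q) * q]   # output length = floor(T / factor)
    return scipy.signal.decimate(x, q, zero_phase=True)


def bandpass(x: np.ndarray, fs: float, low: float, high: float,
             order: int = 2) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass."""
    if not (0 < low < high < fs / 2):
        raise ParameterError(
            f"band edges must satisfy 0 < low < high < fs/2, got "
            f"low={low}, high={high}, fs={fs}"
        )
    sos = scipy.signal.butter(order, [low, high], btype="bandpass", fs=fs,
                              output="sos")
    return scipy.signal.sosfiltfilt(sos, np.asarray(x, dtype=float))


def plan_windows(n_samples: int, cfg: PipelineConfig) -> WindowPlan:
    """Lay out 8-s windows with 2-s hops over ``n_samples`` at fs_target."""
    win = cfg.window_samples
    hop = cfg.shift_samples
    if n_samples < win:
        raise TooShortError(
            f"record has {n_samples} samples at {cfg.fs_target:g} Hz; "
            f"at least {win} (one {cfg.window_s:g}-s window) required"
        )
    n = (n_samples - win) // hop + 1
    slices = [(i * hop, i * hop + win) for i in range(n)]
    return WindowPlan(window_s=cfg.window_s, shift_s=cfg.shift_s,
                      fs_target=cfg.fs_target, slices=slices)


def preprocess(record: SensorRecord, cfg: PipelineConfig):
    """Decimate all channels to fs_target and band-pass filter them.

    Returns ``(ppg, accel)`` arrays of shape (2, T') and (3, T') at
    ``cfg.fs_target``.
    """
    def _prep(ch):
        y = downsample(ch, record.fs, cfg.fs_target)
        return bandpass(y, cfg.fs_target, cfg.bp_low, cfg.bp_high, cfg.bp_order)

    ppg = np.vstack([_prep(record.ppg[i]) for i in range(2)])
    accel = np.vstack([_prep(record.accel[i]) for i in range(3)])
    return ppg, accel
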