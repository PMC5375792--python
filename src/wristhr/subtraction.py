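"""Spectrum subtraction: remove accelerometer-aligned peaks from PPG spectra.

Motion-artifact peaks in the PPG power spectra coincide with peaks of the
acceleration spectra, so after normalizing all spectra to unit energy the
per-bin maximum over the three acceleration spectra (the envelope Acc_l) is
subtracted from each PPG spectrum; everything below one fifth of the
post-subtraction maximum is zeroed.  Analysis is restricted to grid bins
0..max_bin (199 on the 1024-point grid, ~4.86 Hz at 25 Hz sampling, which
covers the 230 BPM physiological ceiling).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

log = logging.getLogger(__name__)


@dataclass
class CleanSpectra:
    s1: np.ndarray        # cleansed PPG1 spectrum, bins 0..max_bin
    s2: np.ndarray        # cleansed PPG2 spectrum
    acc_env: np.ndarray   # per-bin acceleration envelope
    pmax1: float          # pre-threshold maximum of the subtracted PPG1 spectrum
    pmax2: float


def normalize_energy(s: np.ndarray) -> np.ndarray:
    """Scale a nonnegative spectrum so its sum of squared coefficients is 1."""
    s = np.asarray(s, dtype=float)
    norm = np.sqrt(np.sum(s ** 2))
    if norm == 0:
        log.warning("all-zero spectrum passed to normalize_energy (rest window)")
        return s.copy()
    return s / norm


def accel_envelope(sx: np.ndarray, sy: np.ndarray, sz: np.ndarray) -> np.ndarray:
    """Per-bin elementwise maximum of the three acceleration spectra."""
    sx, sy, sz = (np.asarray(a, dtype=float) for a in (sx, sy, sz))
    if not (sx.shape == sy.shape == sz.shape):
        raise ParameterError("acceleration spectra must have equal length")
    return np.maximum(np.maximum(sx, sy), sz)


def subtract_and_threshold(s_ppg: np.ndarray, acc_env: np.ndarray,
                           fraction: float = 0.2):
    """Subtract the envelope, clip at zero and apply the relative threshold.

    d[l] = max(s[l] - Acc[l], 0); pmax = max(d); every d[l] < fraction * pmax
    is zeroed (values exactly equal to the threshold are kept).  Returns
    ``(cleansed, pmax)``.
    """
    s_ppg = np.asarray(s_ppg, dtype=float)
    acc_env = np.asarray(acc_env, dtype=float)
    if s_ppg.shape != acc_env.shape:
        raise ParameterError("spectrum and envelope must have equal length")
    d = np.maximum(s_ppg - acc_env, 0.0)
    pmax = float(d.max(initial=0.0))
    if pmax == 0.0:
        return d, pmax
    d[d < fraction * pmax] = 0.0
    return d, pmax


def clean_spectra(s_ppg: np.ndarray, s_acc: np.ndarray, max_bin: int = 199,
                  fraction: float = 0.2) -> CleanSpectra:
    """Full subtraction stage for one window.

    ``s_ppg`` is (N, 2) and ``s_acc`` is (N, 3) power spectra on the shared
    grid; each spectrum is restricted to bins 0..max_bin and normalized to
    unit energy before the envelope is subtracted.
    """
    b = max_bin + 1
    p1 = normalize_energy(s_ppg[:b, 0])
    p2 = normalize_energy(s_ppg[:b, 1])
    ax = normalize_energy(s_acc[:b, 0])
    ay = normalize_energy(s_acc[:b, 1])
    az = normalize_energy(s_acc[:b, 2])
    env = accel_envelope(ax, ay, az)
    s1, pmax1 = subtract_and_threshold(p1, env, fraction)
    s2, pmax2 = subtract_and_threshold(p2, env, fraction)
    return CleanSpectra(s1=s1, s2=s2, acc_env=env, pmax1=pmax1, pmax2=pmax2)
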