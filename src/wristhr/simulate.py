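"""Synthetic treadmill sessions: structured PPG + accelerometer + truth BPM.

Each session emulates the structure of a wrist recording during a treadmill
protocol: heart rate follows piecewise-linear ramps (rest, moderate, fast,
recover, fast, cool-down); each PPG channel is a sum of decaying cardiac
harmonics driven by the instantaneous heart-rate phase, plus a motion
artifact linearly coupled from the accelerometer axes, plus white noise;
each accelerometer axis carries a drifting cadence sinusoid (fundamental
plus a weak second harmonic) with axis-specific amplitude and phase, plus
noise.  Ground-truth BPM is written per 8-s analysis window (2-s hop) as
the mean instantaneous heart rate over the window.

By default the cadence trajectory tracks 0.5 Hz below the cardiac frequency
(clipped to the configured range), keeping the artifact at least ~0.3 Hz
away from the heart-rate line; ``cadence_mode="crossing"`` instead sweeps
the cadence through the heart-rate frequency for stress testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .errors import ParameterError
from .io import SensorRecord, plan_windows

log = logging.getLogger(__name__)

# HR ramps emulating the treadmill protocol: (duration_s, bpm_start, bpm_end)
DEFAULT_PROTOCOL = (
    (30.0, 80.0, 85.0),     # slow walk
    (60.0, 85.0, 120.0),    # moderate run
    (60.0, 120.0, 155.0),   # fast run
    (60.0, 155.0, 125.0),   # back to moderate
    (60.0, 125.0, 160.0),   # fast again
    (30.0, 160.0, 130.0),   # cool-down
)


@dataclass
class SimConfig:
    duration_s: float = 300.0
    fs: float = 125.0
    hr_protocol: tuple = DEFAULT_PROTOCOL
    cadence_hz_range: tuple = (1.0, 2.8)
    harmonic_amps: tuple = (1.0, 0.4, 0.2)      # cardiac harmonics 1..3
    artifact_gain: tuple = (1.0, 1.0)           # alpha per PPG channel
    coupling: tuple = ((1.0, 0.6, 0.3),         # 2x3 accel -> PPG mixing
                       (0.5, 1.0, 0.4))
    accel_amps: tuple = (1.0, 0.7, 0.5)
    accel_harmonic2: float = 0.3                # relative 2nd cadence harmonic
    accel_noise_sd: float = 0.1
    ppg_noise_sd: float = 0.1
    cadence_mode: str = "tracking"              # or "crossing"
    cadence_offset_hz: float = 0.5
    cadence_drift_hz: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0:
            raise ParameterError("duration_s and fs must be positive")
        if self.cadence_mode not in ("tracking", "crossing"):
            raise ParameterError(f"unknown cadence_mode {self.cadence_mode!r}")
        for _, b0, b1 in self.hr_protocol:
            if not (40.0 <= b0 <= 230.0 and 40.0 <= b1 <= 230.0):
                raise ParameterError(
                    f"protocol BPM values must lie in [40, 230], got {b0}, {b1}"
                )


def hr_trace(cfg: SimConfig) -> np.ndarray:
    """Instantaneous heart rate (BPM) at the raw sampling rate."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    # breakpoints of the piecewise-linear protocol
    times = [0.0]
    bpms = [cfg.hr_protocol[0][1]]
    for dur, b0, b1 in cfg.hr_protocol:
        times.append(times[-1] + dur)
        bpms.append(b1)
    return np.interp(t, times, bpms)


def _cadence_trace(cfg: SimConfig, f_hr: np.ndarray, t: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.cadence_hz_range
    drift = cfg.cadence_drift_hz * np.sin(2 * np.pi * t / 60.0
                                          + rng.uniform(0, 2 * np.pi))
    if cfg.cadence_mode == "tracking":
        cad = f_hr - cfg.cadence_offset_hz + drift
    else:  # crossing: cadence sweeps through the cardiac frequency
        cad = f_hr + 0.3 * np.sin(2 * np.pi * t / 50.0) + drift
    return np.clip(cad, lo, hi)


def simulate_session(cfg: SimConfig,
                     pipeline_cfg: PipelineConfig | None = None):
    """Generate one synthetic session.

    Returns ``(SensorRecord, truth_bpm)``; the truth (one value per analysis
    window under ``pipeline_cfg``'s windowing) is also attached to the
    record.  Fully deterministic for a given ``cfg.seed``.
    """
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    hr = hr_trace(cfg)
    f_hr = hr / 60.0
    phase_hr = 2 * np.pi * np.cumsum(f_hr) / cfg.fs

    cad = _cadence_trace(cfg, f_hr, t, rng)
    phase_cad = 2 * np.pi * np.cumsum(cad) / cfg.fs

    accel_clean = np.empty((3, n))
    for j in range(3):
        psi = rng.uniform(0, 2 * np.pi)
        psi2 = rng.uniform(0, 2 * np.pi)
        accel_clean[j] = cfg.accel_amps[j] * (
            np.sin(phase_cad + psi)
            + cfg.accel_harmonic2 * np.sin(2 * phase_cad + psi2)
        )
    accel = accel_clean + rng.normal(0.0, cfg.accel_noise_sd, size=(3, n))

    coupling = np.asarray(cfg.coupling, dtype=float)
    ppg = np.empty((2, n))
    for h in range(2):
        cardiac = np.zeros(n)
        for k, amp in enumerate(cfg.harmonic_amps, start=1):
            cardiac += amp * np.sin(k * phase_hr + rng.uniform(0, 2 * np.pi))
        artifact = cfg.artifact_gain[h] * (coupling[h] @ accel_clean)
        ppg[h] = cardiac + artifact + rng.normal(0.0, cfg.ppg_noise_sd, size=n)

    truth = window_truth(hr, cfg.fs, pipeline_cfg)
    record = SensorRecord(ppg=ppg, accel=accel, fs=cfg.fs, truth_bpm=truth,
                          subject_id=f"sim{cfg.seed}")
    return record, truth


def window_truth(hr_raw: np.ndarray, fs_raw: float,
                 cfg: PipelineConfig) -> np.ndarray:
    """Per-window truth: mean instantaneous HR over each analysis window."""
    factor = int(round(fs_raw / cfg.fs_target))
    n_target = len(hr_raw) // factor
    plan = plan_windows(n_target, cfg)
    out = np.empty(plan.n_windows)
    for w, (s, e) in enumerate(plan.slices):
        out[w] = float(np.mean(hr_raw[s * factor:e * factor]))
    return out


def simulate_training_corpus(n_sessions: int = 5, seed: int = 0,
                             duration_s: float | None = None,
                             gains=(0.5, 1.0, 1.5, 2.0, 0.8),
                             pipeline_cfg: PipelineConfig | None = None):
    """Labeled (C, S) features pooled from several synthetic sessions.

    Runs the pipeline through candidate discovery on each session, labels
    candidates against the synthetic truth and pools the feature table.
    Returns ``(features (n, 2), labels (n,))``.
    """
    from .model import extract_labeled_features   # avoid import cycle

    if n_sessions < 1:
        raise ParameterError(f"n_sessions must be >= 1, got {n_sessions}")
    pipeline_cfg = pipeline_cfg or PipelineConfig()
    feats, labs = [], []
    for i in range(n_sessions):
        # alternate easy (cadence tracking below HR) and hard (cadence
        # crossing the HR line) regimes so both candidate classes are
        # well represented in the pooled features
        harmonics = ((1.0, 0.4, 0.2), (1.0, 0.7, 0.35), (1.0, 0.55, 0.25))
        sim = SimConfig(
            seed=seed + 101 * i,
            duration_s=duration_s if duration_s is not None else 300.0,
            artifact_gain=(gains[i % len(gains)], gains[i % len(gains)]),
            cadence_mode="crossing" if i % 2 == 1 else "tracking",
            harmonic_amps=harmonics[i % len(harmonics)],
        )
        record, truth = simulate_session(sim, pipeline_cfg)
        f, l = extract_labeled_features(record, pipeline_cfg)
        if len(l) == 0:
            log.warning("session seed=%d yielded no candidates; skipped", sim.seed)
            continue
        feats.append(f)
        labs.append(l)
    if not feats:
        return np.zeros((0, 2)), np.zeros(0, dtype=int)
    return np.vstack(feats), np.concatenate(labs)
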