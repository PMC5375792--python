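"""Pipeline configuration.

All tunable parameters of the estimation pipeline live in a single flat
:class:`PipelineConfig`.  The defaults are the operating point of the method:
8-s analysis windows shifted by 2 s on 25 Hz signals, an order-25 LMS filter
with step size ``mu=0.005``, a redundant DFT grid of ``n_grid=1024`` points,
regularization ``lam=1e-10`` for the sparse solver, candidate threshold
``xi=0.7`` and the 0..199-bin analysis range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    # sampling / preprocessing
    fs_raw: float = 125.0       # Hz, raw recordings
    fs_target: float = 25.0     # Hz, after decimation
    bp_low: float = 0.4         # Hz, Butterworth band-pass lower edge
    bp_high: float = 4.0        # Hz, upper edge
    bp_order: int = 2
    window_s: float = 8.0       # analysis window length, seconds
    shift_s: float = 2.0        # hop between successive windows, seconds

    # adaptive filter
    lms_order: int = 25
    mu: float = 0.005

    # sparse spectral estimation
    tau: float = 1.0            # row-sparsity weight; absorbed by lam in the
                                # regularized iteration (kept for the record)
    lam: float = 1e-10          # regularization of the normal-equation kernel
    p: float = 0.8              # sparsity exponent of M-FOCUSS, in (0, 1]
    n_grid: int = 1024          # redundant DFT grid size N
    mf_max_iter: int = 100
    mf_tol: float = 1e-4        # relative Frobenius change stopping rule
    mf_prune: float = 1e-4      # relative row-norm pruning floor

    # spectrum subtraction
    subtract_fraction: float = 0.2   # pmax/5 relative threshold
    max_bin: int = 199               # analysis restricted to bins 0..max_bin

    # peak tracking
    xi: float = 0.7             # candidate threshold factor (kappa = xi * max)
    pred_step_hz: float = 0.02  # fallback prediction step, Hz per window
    smoother_window: int = 10   # history length for trend extrapolation
    smoother_legacy: int = 20   # legacy smoother knob; recorded, unused
    label_tol_bpm: float = 2.0  # training-label tolerance around truth
    svm_kernel: str = "linear"
    init_band_hz: tuple = (0.5, 3.0)   # plausible resting-to-exercise HR band
    bpm_min: float = 30.0
    bpm_max: float = 230.0

    seed: int = 0

    def __post_init__(self):
        if not (0 < self.bp_low < self.bp_high < self.fs_target / 2):
            raise ParameterError(
                "band edges must satisfy 0 < bp_low < bp_high < fs_target/2, got "
                f"low={self.bp_low}, high={self.bp_high}, fs={self.fs_target}"
            )
        if not (self.window_s > self.shift_s > 0):
            raise ParameterError("require window_s > shift_s > 0")
        if self.n_grid <= self.window_samples:
            raise ParameterError(
                f"n_grid={self.n_grid} must exceed window samples "
                f"{self.window_samples} (redundant dictionary)"
            )
        if not (0 < self.xi < 1):
            raise ParameterError(f"xi must lie in (0, 1), got {self.xi}")
        if not (0 < self.p <= 1):
            raise ParameterError(f"p must lie in (0, 1], got {self.p}")
        if self.lam < 0:
            raise ParameterError("lam must be >= 0")

    @property
    def window_samples(self) -> int:
        """Samples per analysis window at the target rate (8 s * 25 Hz = 200)."""
        return int(round(self.window_s * self.fs_target))

    @property
    def shift_samples(self) -> int:
        return int(round(self.shift_s * self.fs_target))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["init_band_hz"] = list(self.init_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        if "init_band_hz" in d:
            d = dict(d)
            d["init_band_hz"] = tuple(d["init_band_hz"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)
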