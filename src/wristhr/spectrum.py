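"""Sparse line-spectrum estimation on a redundant DFT grid.

The M real samples of a window are modeled as Y = Phi X + V where
Phi[m, n] = exp(j 2 pi m n / N) is an M x N (N > M) redundant DFT dictionary
and X is row-sparse: the two PPG channels (or the three accelerometer
channels) share one sparse set of active frequency rows, a multiple
measurement vector (MMV) problem.  It is solved with the Regularized
M-FOCUSS iteration, an iteratively reweighted least-squares scheme:

    c_k[i]   = || row i of X_k ||_2
    W_{k+1}  = diag(c_k[i]^(1 - p/2))
    A        = Phi W_{k+1}
    Q        = A^H (A A^H + lam I)^{-1} Y
    X_{k+1}  = W_{k+1} Q

which descends the regularized objective ||Y - Phi X||_F^2 + lam * sum_i c_i^p.
The diversity exponent p in (0, 1] controls how aggressively rows are
concentrated; lam stabilizes the M x M kernel inversion.  Rows whose norm
falls below a relative floor are pruned from the active set, which both
sparsifies the solution and keeps the iteration cheap.

Because the measurements are real and the dictionary complex, solutions are
(approximately) conjugate-symmetric: energy at grid bin n mirrors at N - n.
Downstream analysis only reads bins 0..max_bin, well below N/2, so the
mirror half never interferes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import ParameterError


@dataclass(frozen=True)
class DFTDictionary:
    """Redundant DFT dictionary Phi with M rows (time) and N columns (bins)."""

    m: int
    n: int
    phi: np.ndarray = field(repr=False)

    def bin_freq(self, fs: float) -> np.ndarray:
        """Frequency in Hz of each grid column at sampling rate ``fs``."""
        return np.arange(self.n) * fs / self.n


@lru_cache(maxsize=8)
def _dft_dictionary_cached(m: int, n: int) -> DFTDictionary:
    mm, nn = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    phi = np.exp(2j * np.pi * mm * nn / n)
    phi.setflags(write=False)
    return DFTDictionary(m=m, n=n, phi=phi)


def dft_dictionary(m: int, n: int) -> DFTDictionary:
    """Build (and cache) the M x N redundant DFT dictionary."""
    if not (0 < m < n):
        raise ParameterError(
            f"dictionary must be redundant: require 0 < M < N, got M={m}, N={n}"
        )
    return _dft_dictionary_cached(int(m), int(n))


@dataclass
class MFOCUSSConfig:
    lam: float = 1e-10
    p: float = 0.8
    max_iter: int = 100
    tol: float = 1e-4
    prune_thresh: float = 1e-4

    def __post_init__(self):
        if self.lam < 0:
            raise ParameterError("lam must be >= 0")
        if not (0 < self.p <= 1):
            raise ParameterError(f"p must lie in (0, 1], got {self.p}")


@dataclass
class SpectralFrame:
    """Solution of one MMV problem: measurements, coefficients and spectra."""

    Y: np.ndarray             # (M, H) real measurements
    X: np.ndarray             # (N, H) complex row-sparse solution
    S: np.ndarray             # (N, H) power spectra |X|^2
    row_norm: np.ndarray      # (N,) l2 norms of the rows of X
    residual: float           # ||Y - Re(Phi X)||_F
    converged: bool
    n_iter: int
    objective: np.ndarray     # regularized objective per iteration


def mfocuss(Y: np.ndarray, dic: DFTDictionary,
            cfg: MFOCUSSConfig | None = None) -> SpectralFrame:
    """Solve the MMV sparse-recovery problem Y = Phi X + V.

    ``Y`` is (M, H) real (H=2 for the PPG pair, H=3 for the accelerometer).
    Starts from the matched-filter solution X0 = Phi^H Y and iterates the
    reweighted least-squares update until the relative Frobenius change of X
    drops below ``cfg.tol`` or ``cfg.max_iter`` is reached; non-convergence
    is flagged on the frame, not raised.
    """
    cfg = cfg or MFOCUSSConfig()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != dic.m:
        raise ParameterError(
            f"Y has {Y.shape[0]} rows but the dictionary expects {dic.m}"
        )
    if not np.all(np.isfinite(Y)):
        raise ParameterError("Y contains non-finite values")
    n, h = dic.n, Y.shape[1]
    phi = dic.phi

    if not Y.any():
        return SpectralFrame(Y=Y, X=np.zeros((n, h), complex),
                             S=np.zeros((n, h)), row_norm=np.zeros(n),
                             residual=0.0, converged=True, n_iter=0,
                             objective=np.zeros(0))

    active = np.arange(n)
    x = phi.conj().T @ Y            # matched-filter start, (N, H) complex
    eye_m = np.eye(dic.m)
    objective = []
    converged = False
    n_iter = 0
    # rows are pruned only after convergence; in-loop we drop rows whose norm
    # is numerically dead (harder pruning mid-iteration can force the refit
    # onto near-collinear column pairs with huge canceling coefficients)
    dead_floor = min(cfg.prune_thresh ** 2, 1e-8)
    for k in range(cfg.max_iter):
        n_iter = k + 1
        c = np.linalg.norm(x, axis=1)
        keep = c > dead_floor * c.max()
        active = active[keep]
        x = x[keep]
        c = c[keep]
        w = c ** (1.0 - cfg.p / 2.0)
        a = phi[:, active] * w[None, :]
        gram = a @ a.conj().T + cfg.lam * eye_m
        q = a.conj().T @ np.linalg.solve(gram, Y.astype(complex))
        x_new = w[:, None] * q
        delta = np.linalg.norm(x_new - x)
        denom = np.linalg.norm(x)
        resid = Y - phi[:, active] @ x_new
        cnew = np.linalg.norm(x_new, axis=1)
        objective.append(np.linalg.norm(resid) ** 2
                         + cfg.lam * float(np.sum(cnew ** cfg.p)))
        x = x_new
        if denom > 0 and delta / denom < cfg.tol:
            converged = True
            break

    x_full = np.zeros((n, h), dtype=complex)
    x_full[active] = x
    row_norm = np.linalg.norm(x_full, axis=1)
    # final relative pruning of negligible rows
    if row_norm.max() > 0:
        x_full[row_norm < cfg.prune_thresh * row_norm.max()] = 0.0
        row_norm = np.linalg.norm(x_full, axis=1)
    s = np.abs(x_full) ** 2
    residual = float(np.linalg.norm(Y - (phi @ x_full).real))
    return SpectralFrame(Y=Y, X=x_full, S=s, row_norm=row_norm,
                         residual=residual, converged=converged,
                         n_iter=n_iter, objective=np.asarray(objective))


def power_spectrum(frame: SpectralFrame) -> np.ndarray:
    """Per-bin power spectra S[i, h] = |X[i, h]|^2."""
    return np.abs(frame.X) ** 2
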