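"""Motion-artifact reference extraction by principal component analysis.

The three accelerometer channels of an analysis window are standardized,
their correlation matrix is diagonalized with the cyclic Jacobi method, and
the scores of the first principal component become the reference artifact
series a(l) that drives the adaptive filter.  Rest windows (zero-variance
channels) yield a zero reference so the filter passes the PPG through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateChannelError, ParameterError

log = logging.getLogger(__name__)

_VAR_EPS = 1e-12


@dataclass
class PCAResult:
    eigenvalues: np.ndarray    # 3 descending reals; sum = trace = 3
    eigenvectors: np.ndarray   # 3x3, columns orthonormal
    scores: np.ndarray         # first-PC series, length M
    explained_ratio: float     # eigenvalue_1 / 3


def standardize(channels: np.ndarray) -> np.ndarray:
    """Remove the mean and scale each row to unit (population) variance."""
    channels = np.atleast_2d(np.asarray(channels, dtype=float))
    mu = channels.mean(axis=1, keepdims=True)
    sd = channels.std(axis=1, keepdims=True)
    scale = np.max(np.abs(channels), initial=1.0)
    dead = sd.ravel() <= _VAR_EPS * max(scale, 1.0)
    if dead.any():
        raise DegenerateChannelError(
            f"channel(s) {np.flatnonzero(dead).tolist()} have zero variance"
        )
    return (channels - mu) / sd


def correlation_matrix(channels: np.ndarray) -> np.ndarray:
    """Correlation matrix of standardized rows: (1/M) Z Z^T, clipped to [-1,1]."""
    z = np.atleast_2d(np.asarray(channels, dtype=float))
    m = z.shape[1]
    s = (z @ z.T) / m
    s = (s + s.T) / 2
    np.fill_diagonal(s, 1.0)
    return np.clip(s, -1.0, 1.0)


def jacobi_eig(s: np.ndarray, tol: float = 1e-12, max_sweeps: int = 100):
    """Eigen-decomposition of a small symmetric matrix by cyclic Jacobi rotations.

    Returns ``(eigenvalues, eigenvectors)`` with eigenvalues sorted descending
    and eigenvectors as the corresponding columns.  Rotations are applied
    until every off-diagonal element is below ``tol``.
    """
    a = np.array(s, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ParameterError("jacobi_eig expects a square matrix")
    if np.max(np.abs(a - a.T)) > 1e-9:
        raise ParameterError("jacobi_eig expects a symmetric matrix")
    n = a.shape[0]
    v = np.eye(n)
    for _ in range(max_sweeps):
        off = np.max(np.abs(a - np.diag(np.diag(a)))) if n > 1 else 0.0
        if off < tol:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                apq = a[p, q]
                if abs(apq) < tol:
                    continue
                theta = (a[q, q] - a[p, p]) / (2.0 * apq)
                t = np.sign(theta) / (abs(theta) + np.hypot(theta, 1.0))
                if theta == 0.0:
                    t = 1.0
                c = 1.0 / np.sqrt(t * t + 1.0)
                sn = t * c
                rot = np.eye(n)
                rot[p, p] = rot[q, q] = c
                rot[p, q] = sn
                rot[q, p] = -sn
                a = rot.T @ a @ rot
                v = v @ rot
    vals = np.diag(a).copy()
    order = np.argsort(vals)[::-1]
    return vals[order], v[:, order]


def first_pc_reference(accel_window: np.ndarray):
    """Reference artifact series a(l) from a 3 x M accelerometer window.

    Returns ``(a, PCAResult)``.  The reference is the first-PC score series,
    sign-normalized so its correlation with the first accelerometer channel
    is non-negative, then scaled to unit variance.  If any channel is
    degenerate (rest window) a zero reference is returned.
    """
    accel_window = np.atleast_2d(np.asarray(accel_window, dtype=float))
    m = accel_window.shape[1]
    try:
        z = standardize(accel_window)
    except DegenerateChannelError:
        log.warning("degenerate accelerometer window; using zero reference")
        zeros = np.zeros(m)
        return zeros, PCAResult(
            eigenvalues=np.array([1.0, 1.0, 1.0]),
            eigenvectors=np.eye(3),
            scores=zeros,
            explained_ratio=1.0 / 3.0,
        )
    corr = correlation_matrix(z)
    vals, vecs = jacobi_eig(corr)
    v1 = vecs[:, 0]
    scores = v1 @ z
    if scores @ z[0] < 0:   # sign convention: corr(a, accx) >= 0
        scores = -scores
        v1 = -v1
        vecs = vecs.copy()
        vecs[:, 0] = v1
    sd = scores.std()
    a = scores / sd if sd > 0 else scores
    log.debug("PCA eigenvalues %s (explained %.3f)", vals, vals[0] / 3.0)
    return a, PCAResult(
        eigenvalues=vals,
        eigenvectors=vecs,
        scores=scores,
        explained_ratio=float(vals[0] / 3.0),
    )
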