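"""Adaptive least-mean-squares cancellation of the motion artifact.

The observed PPG is modeled as y(l) = y0(l) + m(l), cardiac signal plus
artifact.  An order-P tap-delay filter predicts the artifact from the
accelerometer-derived reference a(l):

    m'(l) = w(l)^T [a(l), a(l-1), ..., a(l-P+1)]
    e(l)  = y(l) - m'(l)
    w(l+1) = w(l) + mu * e(l) * a_vec(l)

and the error e(l) is the cleansed PPG.  The update sign is the one that
performs stochastic gradient descent on e(l)^2 (see docs/methods.md for the
sign-convention note).  A zero reference makes the filter an exact
pass-through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError, ParameterError


@dataclass
class LMSState:
    weights: np.ndarray            # final tap weights, length = order
    order: int
    mu: float
    error: np.ndarray              # e(l): the cleansed output series
    artifact_estimate: np.ndarray  # m'(l)


def lms_denoise(y: np.ndarray, a: np.ndarray, order: int = 25,
                mu: float = 0.005, w0: np.ndarray | None = None):
    """Run the LMS recursion over ``y`` with reference ``a``.

    Returns ``(cleansed, LMSState)``.  ``w0`` lets successive windows of a
    session continue the recursion from the previous window's weights.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    if y.shape != a.shape or y.ndim != 1:
        raise ParameterError(
            f"signal and reference must be 1-D and equal length, got "
            f"{y.shape} vs {a.shape}"
        )
    m = len(y)
    if m < order:
        raise ParameterError(f"need at least order={order} samples, got {m}")
    if w0 is None:
        w = np.zeros(order)
    else:
        w = np.array(w0, dtype=float)
        if w.shape != (order,):
            raise ParameterError("w0 length must equal the filter order")

    if not a.any():
        # zero reference: update vanishes, bitwise pass-through
        return y.copy(), LMSState(weights=w, order=order, mu=mu,
                                  error=y.copy(), artifact_estimate=np.zeros(m))

    apad = np.concatenate([np.zeros(order - 1), a])
    e = np.empty(m)
    mhat = np.empty(m)
    with np.errstate(over="ignore", invalid="ignore"):  # guarded explicitly
        for l in range(m):
            h = apad[l:l + order][::-1]   # [a(l), a(l-1), ..., a(l-P+1)]
            mhat[l] = w @ h
            e[l] = y[l] - mhat[l]
            if not np.isfinite(e[l]):
                raise DivergenceError(step=l, mu=mu)
            w = w + mu * e[l] * h
    if not np.all(np.isfinite(w)):
        raise DivergenceError(step=m - 1, mu=mu)
    return e, LMSState(weights=w, order=order, mu=mu, error=e,
                       artifact_estimate=mhat)


def suppression_db(y: np.ndarray, e: np.ndarray, tail: float = 0.25) -> float:
    """Artifact suppression in dB over the final ``tail`` fraction of a run."""
    n = len(y)
    k = max(1, int(n * (1 - tail)))
    pin = float(np.mean(np.asarray(y, float)[k:] ** 2))
    pout = float(np.mean(np.asarray(e, float)[k:] ** 2))
    if pout == 0:
        return np.inf
    return 10.0 * np.log10(pin / pout)
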