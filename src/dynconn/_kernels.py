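"""Numba-compiled recursions for the GARCH(1,1) and DCC(1,1) quasi-likelihoods.

These are the innermost loops of the estimator: a scalar variance recursion
per node and a scalar correlation recursion per node pair, each evaluated
hundreds of times inside the optimizer. Everything here is pure float64
arithmetic with no allocation inside the time loop.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "garch11_filter",
    "garch11_nll",
    "dcc11_rho",
    "dcc11_nll",
]

_RHO_CLAMP = 1.0 - 1e-6


@njit(cache=True)
def garch11_filter(omega: float, alpha: float, beta: float, y: np.ndarray, s2_init: float) -> np.ndarray:
    """Conditional variances sigma^2_t under sigma^2_t = omega + alpha*y_{t-1}^2 + beta*sigma^2_{t-1}.

    The recursion is seeded with sigma^2_0 = s2_init for the first observation.
    """
    T = y.shape[0]
    s2 = np.empty(T)
    s2[0] = s2_init
    for t in range(1, T):
        s2[t] = omega + alpha * y[t - 1] * y[t - 1] + beta * s2[t - 1]
    return s2


@njit(cache=True)
def garch11_nll(omega: float, alpha: float, beta: float, y: np.ndarray, s2_init: float) -> float:
    """Gaussian negative quasi-log-likelihood (constants dropped)."""
    T = y.shape[0]
    s2 = s2_init
    nll = 0.0
    for t in range(T):
        if t > 0:
            s2 = omega + alpha * y[t - 1] * y[t - 1] + beta * s2
        if s2 <= 0.0 or not np.isfinite(s2):
            return 1e30
        nll += 0.5 * (np.log(s2) + y[t] * y[t] / s2)
    return nll


@njit(cache=True)
def dcc11_rho(a: float, b: float, e1: np.ndarray, e2: np.ndarray, qbar: float) -> np.ndarray:
    """Conditional correlation path of the bivariate DCC(1,1) recursion.

    Q_t = (1 - a - b) * Qbar + a * eps_{t-1} eps'_{t-1} + b * Q_{t-1},
    started at Q_0 = Qbar (unit diagonal, off-diagonal ``qbar``), rescaled to
    a correlation at every step: rho_t = q12_t / sqrt(q11_t * q22_t).
    """
    T = e1.shape[0]
    rho = np.empty(T)
    omega = 1.0 - a - b
    q11 = 1.0
    q22 = 1.0
    q12 = qbar
    for t in range(T):
        r = q12 / np.sqrt(q11 * q22)
        if r > _RHO_CLAMP:
            r = _RHO_CLAMP
        elif r < -_RHO_CLAMP:
            r = -_RHO_CLAMP
        rho[t] = r
        q11 = omega + a * e1[t] * e1[t] + b * q11
        q22 = omega + a * e2[t] * e2[t] + b * q22
        q12 = omega * qbar + a * e1[t] * e2[t] + b * q12
    return rho


@njit(cache=True)
def dcc11_nll(a: float, b: float, e1: np.ndarray, e2: np.ndarray, qbar: float) -> float:
    """Negative of the correlation-stage Gaussian quasi-log-likelihood.

    Per-step contribution 0.5 * [log(1 - r^2) + (e1^2 + e2^2 - 2 r e1 e2)/(1 - r^2)];
    terms not involving (a, b) are dropped.
    """
    T = e1.shape[0]
    omega = 1.0 - a - b
    q11 = 1.0
    q22 = 1.0
    q12 = qbar
    nll = 0.0
    for t in range(T):
        r = q12 / np.sqrt(q11 * q22)
        if r > _RHO_CLAMP:
            r = _RHO_CLAMP
        elif r < -_RHO_CLAMP:
            r = -_RHO_CLAMP
        d = 1.0 - r * r
        nll += 0.5 * (np.log(d) + (e1[t] * e1[t] + e2[t] * e2[t] - 2.0 * r * e1[t] * e2[t]) / d)
        if not np.isfinite(nll):
            return 1e30
        q11 = omega + a * e1[t] * e1[t] + b * q11
        q22 = omega + a * e2[t] * e2[t] + b * q22
        q12 = omega * qbar + a * e1[t] * e2[t] + b * q12
    return nll
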