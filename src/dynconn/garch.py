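"""ARIMA pre-whitening and univariate GARCH(1,1) volatility estimation.

This is the first two steps of the dynamic-conditional-correlation pipeline:
each node signal is detrended with an ARIMA model so the volatility model
operates on approximately mean-zero innovations, then a GARCH(1,1) model

    y_t = sigma_t * eps_t,      sigma^2_t = omega + alpha * y^2_{t-1} + beta * sigma^2_{t-1}

with omega > 0, alpha >= 0, beta >= 0, alpha + beta < 1 is fitted to each
detrended series by Gaussian quasi-maximum likelihood. Standardized
residuals y_t / sigma_t feed the DCC correlation stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._kernels import garch11_filter, garch11_nll

logger = logging.getLogger(__name__)

__all__ = ["GarchFit", "arima_detrend", "fit_garch11"]

#: lower bound keeping alpha + beta strictly inside the stationarity region
_STATIONARITY_MARGIN = 1e-6


@dataclass
class GarchFit:
    """Fitted GARCH(1,1) model for one detrended node series."""

    omega: float
    alpha: float
    beta: float
    cond_sd: np.ndarray
    std_residuals: np.ndarray
    loglik: float
    converged: bool
    arima_order: tuple[int, int, int] | None = None

    @property
    def unconditional_variance(self) -> float:
        return self.omega / (1.0 - self.alpha - self.beta)

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta >= 1:
            raise ValueError("GARCH parameters must satisfy alpha, beta >= 0 and alpha + beta < 1")


def arima_detrend(
    series: np.ndarray,
    order: tuple[int, int, int] = (1, 0, 1),
    method: str = "statespace",
) -> np.ndarray:
    """Residuals of a maximum-likelihood ARIMA fit of the given order.

    Parameters
    ----------
    series
        One node's signal, length T.
    order
        (p, d, q) ARIMA order. ``(0, 0, 0)`` reduces to mean removal.
    method
        Estimation method forwarded to :class:`statsmodels.tsa.arima.model.ARIMA`.

    A non-convergent fit falls back to mean removal with a warning; a constant
    series returns zeros.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    p, d, q = order
    if series.shape[0] <= 10 * (p + q + 1):
        raise ValueError(f"series too short (T={series.shape[0]}) for ARIMA order {order}")
    if np.ptp(series) == 0.0:
        logger.warning("constant series passed to arima_detrend; returning zeros")
        return np.zeros_like(series)
    if order == (0, 0, 0):
        return series - series.mean()

    from statsmodels.tsa.arima.model import ARIMA

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ARIMA(series, order=order, trend="c" if d == 0 else "n").fit(method=method)
        resid = np.asarray(res.resid, dtype=float)
        if not np.all(np.isfinite(resid)):
            raise RuntimeError("non-finite residuals")
        return resid
    except Exception as exc:  # statsmodels raises several optimizer/linalg error types
        logger.warning("ARIMA%s fit failed (%s); falling back to mean removal", order, exc)
        return series - series.mean()


def _fit_garch_once(y: np.ndarray, x0: np.ndarray, s2_init: float, variance_targeting: bool):
    var = float(np.var(y))
    if variance_targeting:
        # omega implied by the sample variance: omega = var * (1 - alpha - beta).
        # Removes the flat near-unit-root ridge (beta -> 1, omega -> 0) of the
        # free-omega likelihood, which is untethered on quiet series.
        bounds = [(0.0, 1.0 - _STATIONARITY_MARGIN)] * 2
        constraint = {"type": "ineq", "fun": lambda p: 1.0 - _STATIONARITY_MARGIN - p[0] - p[1]}
        return minimize(
            lambda p: garch11_nll(var * (1.0 - p[0] - p[1]), p[0], p[1], y, s2_init),
            x0[1:],
            method="SLSQP",
            bounds=bounds,
            constraints=[constraint],
            options={"maxiter": 200, "ftol": 1e-10},
        )
    bounds = [(1e-12, 10.0 * var), (0.0, 1.0 - _STATIONARITY_MARGIN), (0.0, 1.0 - _STATIONARITY_MARGIN)]
    constraint = {
        "type": "ineq",
        "fun": lambda p: 1.0 - _STATIONARITY_MARGIN - p[1] - p[2],
    }
    return minimize(
        lambda p: garch11_nll(p[0], p[1], p[2], y, s2_init),
        x0,
        method="SLSQP",
        bounds=bounds,
        constraints=[constraint],
        options={"maxiter": 200, "ftol": 1e-10},
    )


def fit_garch11(
    residuals: np.ndarray,
    n_restarts: int = 3,
    seed: int = 0,
    variance_targeting: bool = True,
) -> GarchFit:
    """Gaussian quasi-maximum-likelihood GARCH(1,1) fit.

    By default omega is profiled out by variance targeting
    (omega = sample_var * (1 - alpha - beta)), the standard stabilization of
    the quasi-likelihood; ``variance_targeting=False`` estimates all three
    parameters freely. The recursion is initialized at the sample variance;
    optimization starts at (0.1 * var, 0.05, 0.90) with up to ``n_restarts``
    jittered restarts. On optimizer failure the fit degrades to constant
    variance (alpha = beta = 0, omega = sample variance) with
    ``converged=False``.
    """
    y = np.asarray(residuals, dtype=float)
    if y.ndim != 1:
        raise ValueError("residuals must be one-dimensional")
    if y.shape[0] < 100:
        raise ValueError(f"need at least 100 observations to fit GARCH(1,1); got {y.shape[0]}")
    if np.ptp(y) == 0.0:
        raise ValueError("residuals are constant; GARCH fit is undefined")

    var = float(np.var(y))
    s2_init = var
    rng = np.random.default_rng(seed)
    x0 = np.array([0.1 * var, 0.05, 0.90])
    best = None
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else np.array(
            [
                x0[0] * rng.uniform(0.3, 3.0),
                min(0.3, x0[1] * rng.uniform(0.2, 4.0)),
                rng.uniform(0.3, 0.95),
            ]
        )
        if start[1] + start[2] >= 1.0 - _STATIONARITY_MARGIN:
            start[2] = 1.0 - _STATIONARITY_MARGIN - start[1] - 0.01
        try:
            res = _fit_garch_once(y, start, s2_init, variance_targeting)
        except Exception:
            continue
        if res.success and np.isfinite(res.fun):
            best = res
            break

    if best is None:
        logger.warning("GARCH(1,1) optimization failed after restarts; using constant variance")
        sd = np.full_like(y, np.sqrt(var))
        return GarchFit(
            omega=var,
            alpha=0.0,
            beta=0.0,
            cond_sd=sd,
            std_residuals=y / sd,
            loglik=-garch11_nll(var, 0.0, 0.0, y, var),
            converged=False,
        )

    if variance_targeting:
        alpha, beta = (float(v) for v in best.x)
        omega = var * (1.0 - alpha - beta)
    else:
        omega, alpha, beta = (float(v) for v in best.x)
    omega = max(omega, 1e-12)
    alpha = max(alpha, 0.0)
    beta = max(beta, 0.0)
    s2 = garch11_filter(omega, alpha, beta, y, s2_init)
    cond_sd = np.sqrt(s2)
    return GarchFit(
        omega=omega,
        alpha=alpha,
        beta=beta,
        cond_sd=cond_sd,
        std_residuals=y / cond_sd,
        loglik=-float(best.fun),
        converged=True,
    )
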