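"""Bivariate dynamic conditional correlation (DCC) estimation.

The conditional correlation between two standardized-residual series is
modelled with the DCC(1,1) recursion

    Q_t = (1 - a - b) * Qbar + a * eps_{t-1} eps'_{t-1} + b * Q_{t-1}

with Qbar the sample correlation matrix of the residual pair, rescaled to a
correlation matrix R_t = diag(Q_t)^{-1/2} Q_t diag(Q_t)^{-1/2} at every
timepoint, so the connectivity estimate has the same temporal resolution as
the input signals. (a, b) are estimated by Gaussian quasi-maximum likelihood
under a >= 0, b >= 0, a + b < 1. Estimation is two-stage: univariate
GARCH(1,1) fits standardize each node series first (see :mod:`dynconn.garch`),
then each unordered node pair is fitted independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from ._kernels import dcc11_nll, dcc11_rho
from .containers import NodeTimeSeriesSet, node_pairs
from .garch import GarchFit, arima_detrend, fit_garch11

logger = logging.getLogger(__name__)

__all__ = ["DccSeries", "fit_dcc_pair", "dcc_all_pairs"]

_MARGIN = 1e-6


@dataclass
class DccSeries:
    """Conditional-correlation path and DCC(1,1) parameters for one node pair."""

    pair: tuple[int, int]
    rho: np.ndarray
    a: float
    b: float
    loglik: float
    converged: bool

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b >= 1:
            raise ValueError("DCC parameters must satisfy a, b >= 0 and a + b < 1")
        if np.any(np.abs(self.rho) >= 1):
            raise ValueError("conditional correlations must lie strictly in (-1, 1)")


def _standardize(e: np.ndarray) -> np.ndarray:
    sd = e.std()
    if sd == 0:
        raise ValueError("standardized residuals are constant")
    return e / sd


def fit_dcc_pair(
    eps_i: np.ndarray,
    eps_j: np.ndarray,
    n_restarts: int = 3,
    seed: int = 0,
    pair: tuple[int, int] = (0, 1),
) -> DccSeries:
    """Fit the bivariate DCC(1,1) recursion to a pair of standardized residuals.

    On optimizer failure the correlation path is frozen at the sample
    correlation (a = b = 0) and flagged ``converged=False``.
    """
    e1 = _standardize(np.asarray(eps_i, dtype=float))
    e2 = _standardize(np.asarray(eps_j, dtype=float))
    if e1.shape != e2.shape or e1.ndim != 1:
        raise ValueError("residual series must be one-dimensional and of equal length")
    T = e1.shape[0]
    if T < 100:
        raise ValueError(f"need at least 100 timepoints; got {T}")

    qbar = float(np.corrcoef(e1, e2)[0, 1])
    qbar = float(np.clip(qbar, -1 + _MARGIN, 1 - _MARGIN))

    bounds = [(0.0, 1.0 - _MARGIN), (0.0, 1.0 - _MARGIN)]
    constraint = {"type": "ineq", "fun": lambda p: 1.0 - _MARGIN - p[0] - p[1]}
    rng = np.random.default_rng(seed)
    x0 = np.array([0.05, 0.90])
    best = None
    for attempt in range(n_restarts + 1):
        start = x0 if attempt == 0 else np.array([rng.uniform(0.0, 0.2), rng.uniform(0.3, 0.95)])
        if start.sum() >= 1.0 - _MARGIN:
            start[1] = 1.0 - _MARGIN - start[0] - 0.01
        try:
            res = minimize(
                lambda p: dcc11_nll(p[0], p[1], e1, e2, qbar),
                start,
                method="SLSQP",
                bounds=bounds,
                constraints=[constraint],
                options={"maxiter": 200, "ftol": 1e-10},
            )
        except Exception:
            continue
        if res.success and np.isfinite(res.fun):
            best = res
            break

    if best is None:
        logger.warning("DCC optimization failed for pair %s; freezing at sample correlation", pair)
        rho = np.full(T, qbar)
        return DccSeries(
            pair=pair,
            rho=rho,
            a=0.0,
            b=0.0,
            loglik=-float(dcc11_nll(0.0, 0.0, e1, e2, qbar)),
            converged=False,
        )

    a, b = (max(float(v), 0.0) for v in best.x)
    rho = dcc11_rho(a, b, e1, e2, qbar)
    return DccSeries(pair=pair, rho=rho, a=a, b=b, loglik=-float(best.fun), converged=True)


def dcc_all_pairs(
    ts: NodeTimeSeriesSet,
    arima_order: tuple[int, int, int] = (1, 0, 1),
    arima_method: str = "statespace",
    n_restarts: int = 3,
    seed: int = 0,
) -> list[DccSeries]:
    """Detrend and GARCH-fit each node once, then fit every unordered pair.

    Runs are concatenated before fitting. Returns K*(K-1)/2 :class:`DccSeries`
    in lexicographic pair order; per-pair failures are flagged (frozen at the
    sample correlation), never raised.
    """
    garch_fits: list[GarchFit] = []
    for k in range(ts.n_nodes):
        resid = arima_detrend(ts.data[:, k], order=arima_order, method=arima_method)
        if np.ptp(resid) == 0.0:
            # degenerate (constant) node: unit-variance noise-free placeholder
            fit = GarchFit(
                omega=1.0,
                alpha=0.0,
                beta=0.0,
                cond_sd=np.ones(ts.n_timepoints),
                std_residuals=np.zeros(ts.n_timepoints),
                loglik=0.0,
                converged=False,
                arima_order=arima_order,
            )
        else:
            fit = fit_garch11(resid, n_restarts=n_restarts, seed=seed)
            fit.arima_order = arima_order
        garch_fits.append(fit)

    out: list[DccSeries] = []
    for i, j in node_pairs(ts.n_nodes):
        try:
            out.append(
                fit_dcc_pair(
                    garch_fits[i].std_residuals,
                    garch_fits[j].std_residuals,
                    n_restarts=n_restarts,
                    seed=seed,
                    pair=(i, j),
                )
            )
        except Exception as exc:
            logger.warning("DCC pair (%d, %d) failed for subject %s: %s", i, j, ts.subject_id, exc)
            out.append(
                DccSeries(
                    pair=(i, j),
                    rho=np.zeros(ts.n_timepoints),
                    a=0.0,
                    b=0.0,
                    loglik=float("nan"),
                    converged=False,
                )
            )
    return out
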