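"""Excursion-based non-stationarity statistic (T-index) for correlation series.

A connection's conditional-correlation series rho_t is summarized by its
excursions from the overall median: an excursion is the segment between two
consecutive crossings of the median, with length tau (timepoints between the
crossings) and magnitude h (peak absolute deviation from the median within
the segment). The T-index is the mean of h_i * tau_i over the N complete
excursions,

    T = (1/N) * sum_i h_i * tau_i,

so a connection scores high when its correlation departs from its median
often, far, or for long — regardless of the sign of the departure or of the
median level itself. A series with no complete excursion gets T = 0.

Conventions (deterministic, documented): a crossing is recorded at the index
of the later of two consecutive samples whose deviations from the median have
opposite signs; a sample lying exactly on the median is itself a crossing
point (it terminates the running excursion); the partial segments before the
first and after the last crossing are discarded; a segment that never leaves
the median (h = 0, e.g. every sample of a constant series) is not an
excursion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Excursion",
    "ExcursionSet",
    "find_excursions",
    "compute_tindex",
    "tindex",
    "tindex_table",
    "session_consistency",
]


@dataclass(frozen=True)
class Excursion:
    tau: int
    h: float
    direction: str  # "above" | "below"


@dataclass
class ExcursionSet:
    median_value: float
    crossings: list[int]
    excursions: list[Excursion]

    @property
    def N(self) -> int:
        return len(self.excursions)


def find_excursions(rho: np.ndarray) -> ExcursionSet:
    """Locate all complete excursions of ``rho`` around its full-series median."""
    rho = np.asarray(rho, dtype=float)
    if rho.ndim != 1 or rho.shape[0] < 3:
        raise ValueError("rho must be a 1-D series with at least 3 samples")
    if not np.all(np.isfinite(rho)):
        raise ValueError("rho contains non-finite values")

    med = float(np.median(rho))
    dev = rho - med
    sign = np.sign(dev)

    # crossing indices: zero samples, plus later samples of opposite-sign
    # consecutive nonzero pairs (zeros already break the sign run)
    crossings: list[int] = []
    prev_nonzero = 0.0
    for t in range(rho.shape[0]):
        s = sign[t]
        if s == 0.0:
            if t > 0:
                crossings.append(t)
            prev_nonzero = 0.0
        else:
            if prev_nonzero != 0.0 and s != prev_nonzero and t > 0:
                crossings.append(t)
            prev_nonzero = s

    excursions: list[Excursion] = []
    for c0, c1 in zip(crossings[:-1], crossings[1:]):
        seg = dev[c0:c1]
        k = int(np.argmax(np.abs(seg)))
        h = float(abs(seg[k]))
        if h == 0.0:
            # segment glued to the median: no departure, hence no excursion
            continue
        direction = "above" if seg[k] > 0 else "below"
        excursions.append(Excursion(tau=c1 - c0, h=h, direction=direction))

    return ExcursionSet(median_value=med, crossings=crossings, excursions=excursions)


def compute_tindex(exc: ExcursionSet, tr_seconds: float | None = None) -> float:
    """Mean of h * tau over complete excursions; 0 when there are none.

    With ``tr_seconds`` given, tau is expressed in seconds rather than
    timepoints (a pure rescaling of the index).
    """
    if exc.N == 0:
        return 0.0
    scale = tr_seconds if tr_seconds is not None else 1.0
    return float(np.mean([e.h * e.tau * scale for e in exc.excursions]))


def tindex(rho: np.ndarray, tr_seconds: float | None = None) -> float:
    """Convenience: T-index of a correlation series in one call."""
    return compute_tindex(find_excursions(rho), tr_seconds=tr_seconds)


def tindex_table(
    dcc_results: dict[str, list],
    n_nodes: int | None = None,
    tr_seconds: float | None = None,
) -> pd.DataFrame:
    """Assemble the subject x connection T-index table.

    ``dcc_results`` maps subject id -> list of :class:`~dynconn.dcc.DccSeries`
    in lexicographic pair order. Non-converged pairs with a degenerate
    (length-0 or constant) path are recorded as missing. Columns are named
    ``"i_j"`` with 1-based node indices.
    """
    if not dcc_results:
        raise ValueError("no DCC results supplied")
    pair_sets = {tuple(d.pair for d in series) for series in dcc_results.values()}
    if len(pair_sets) != 1:
        raise ValueError("inconsistent node pairs across subjects")
    pairs = next(iter(pair_sets))
    if n_nodes is not None:
        expected = n_nodes * (n_nodes - 1) // 2
        if len(pairs) != expected:
            raise ValueError(f"expected {expected} pairs for {n_nodes} nodes, got {len(pairs)}")

    columns = [f"{i + 1}_{j + 1}" for i, j in pairs]
    rows = {}
    for subject, series_list in dcc_results.items():
        vals = []
        for d in series_list:
            if not d.converged and (d.rho.size == 0 or np.ptp(d.rho) == 0.0):
                logger.warning("subject %s pair %s not converged; recording missing T", subject, d.pair)
                vals.append(np.nan)
            else:
                vals.append(tindex(d.rho, tr_seconds=tr_seconds))
        rows[subject] = vals
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "subject_id"
    return table


def session_consistency(rho: np.ndarray, split_at: int | None = None) -> tuple[float, float, float]:
    """T-index computed separately on the two halves of a series.

    Returns (T_first_half, T_second_half, absolute difference). ``split_at``
    defaults to the midpoint; it must lie strictly inside the series.
    """
    rho = np.asarray(rho, dtype=float)
    T = rho.shape[0]
    if split_at is None:
        split_at = T // 2
    if not (3 <= split_at <= T - 3):
        raise ValueError(f"split index {split_at} leaves a half too short (T={T})")
    t1 = tindex(rho[:split_at])
    t2 = tindex(rho[split_at:])
    return t1, t2, abs(t1 - t2)
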