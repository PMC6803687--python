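"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import dynconn as dc


def brute_force_excursions(rho: np.ndarray) -> tuple[list[tuple[int, float]], float]:
    """Independent excursion scanner: walk the series sample by sample.

    Returns ([(tau, h), ...], median). Conventions: deviations from the
    full-series median; a crossing sits at the later sample of an
    opposite-sign pair, or at any sample lying exactly on the median; only
    segments between two consecutive crossings count.
    """
    rho = np.asarray(rho, dtype=float)
    med = float(np.median(rho))
    dev = rho - med
    crossings = []
    last_sign = 0.0
    for t, d in enumerate(dev):
        if d == 0.0:
            if t > 0:
                crossings.append(t)
            last_sign = 0.0
        else:
            s = 1.0 if d > 0 else -1.0
            if last_sign != 0.0 and s != last_sign and t > 0:
                crossings.append(t)
            last_sign = s
    out = []
    for a, b in zip(crossings[:-1], crossings[1:]):
        h = max(abs(float(d)) for d in dev[a:b])
        if h > 0.0:  # a segment glued to the median is not an excursion
            out.append((b - a, h))
    return out, med


def brute_force_tindex(rho: np.ndarray) -> float:
    exc, _ = brute_force_excursions(rho)
    if not exc:
        return 0.0
    return float(np.mean([tau * h for tau, h in exc]))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort_tindex():
    """T-index table of a 20-subject cohort at the full default dimensions.

    Default config: 15 nodes, 4 runs x 1,200 timepoints, three sinusoidal
    dynamic pairs and three constant-correlation stationary pairs. Shared
    across the discrimination and connection-count checks because the DCC
    stage over all 105 pairs per subject is the expensive part of the suite.
    """
    config = dc.CohortConfig(n_subjects=20, seed=11)
    phen = dc.simulate_phenotypes(config)
    series = dc.simulate_node_timeseries(config, phen)
    dcc_results = {sid: dc.dcc_all_pairs(ts) for sid, ts in series.items()}
    table = dc.tindex_table(dcc_results, n_nodes=config.n_nodes)
    return config, phen, table


@pytest.fixture(scope="session")
def small_phenotypes():
    config = dc.CohortConfig(n_subjects=400, n_nodes=2, seed=3)
    return dc.simulate_phenotypes(config)
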