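"""Line-plot diagnostics for conditional-correlation series and excursions."""

from __future__ import annotations

import numpy as np

from .tindex import ExcursionSet, find_excursions

__all__ = ["plot_dcc_series", "plot_excursions"]


def plot_dcc_series(rho: np.ndarray, ax=None, **kwargs):
    """Conditional correlation over time with its median as a dashed line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(np.asarray(rho), lw=0.8, **kwargs)
    ax.axhline(float(np.median(rho)), ls="--", color="k", lw=0.8)
    ax.set_xlabel("timepoint")
    ax.set_ylabel(r"$\rho_t$")
    return ax


def plot_excursions(rho: np.ndarray, exc: ExcursionSet | None = None, ax=None):
    """DCC series with each complete excursion shaded and its peak marked."""
    import matplotlib.pyplot as plt

    rho = np.asarray(rho, dtype=float)
    if exc is None:
        exc = find_excursions(rho)
    ax = plot_dcc_series(rho, ax=ax)
    for c0, c1, e in zip(exc.crossings[:-1], exc.crossings[1:], exc.excursions):
        color = "tab:orange" if e.direction == "above" else "tab:blue"
        ax.axvspan(c0, c1, alpha=0.15, color=color)
        seg = np.abs(rho[c0:c1] - exc.median_value)
        peak = c0 + int(np.argmax(seg))
        ax.plot([peak], [rho[peak]], "o", ms=3, color=color)
    ax.set_title(f"{exc.N} excursions, median {exc.median_value:.3f}")
    return ax
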