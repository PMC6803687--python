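"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NodeTimeSeriesSet", "node_pairs"]


def node_pairs(n_nodes: int) -> list[tuple[int, int]]:
    """All unordered node pairs (i < j, 0-based) in lexicographic order."""
    return [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]


@dataclass
class NodeTimeSeriesSet:
    """One subject's node time series: a T x K matrix plus run structure.

    ``run_boundaries`` holds the start index of each run; runs are
    concatenated along the time axis.
    """

    subject_id: str
    data: np.ndarray
    run_boundaries: list[int] = field(default_factory=lambda: [0])
    tr_seconds: float = 0.72

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x K matrix")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 nodes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.run_boundaries or self.run_boundaries[0] != 0:
            raise ValueError("run_boundaries must start at 0")
        if list(self.run_boundaries) != sorted(set(self.run_boundaries)):
            raise ValueError("run_boundaries must be strictly increasing")
        if self.run_boundaries[-1] >= self.data.shape[0]:
            raise ValueError("run boundary beyond series length")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)
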