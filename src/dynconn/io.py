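"""File formats: node-time-series text matrices, CSV tables, JSON sidecars.

The node-time-series dialect is a plain whitespace-delimited text matrix, one
row per timepoint and one column per node, no header — one file per subject.
Node indices are 1-based in every file written (``i_j`` connection names);
in-memory indices are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import NodeTimeSeriesSet
from .dcc import DccSeries

__all__ = [
    "read_node_timeseries",
    "write_node_timeseries",
    "write_cohort",
    "read_manifest",
    "write_dcc_params",
    "write_dcc_series",
    "write_excursion_diagnostics",
    "write_tindex_table",
    "read_tindex_table",
]


class ParseError(ValueError):
    pass


def read_node_timeseries(
    path: str | Path,
    n_runs: int = 4,
    tr_seconds: float = 0.72,
    subject_id: str | None = None,
) -> NodeTimeSeriesSet:
    """Read one subject's T x K whitespace-delimited node-time-series file.

    Run boundaries are imposed as ``n_runs`` equal segments. Ragged rows,
    non-numeric tokens, and non-finite values raise :class:`ParseError`
    naming the offending line.
    """
    path = Path(path)
    rows: list[np.ndarray] = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = np.asarray(tokens, dtype=float)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric token ({exc})") from None
            if width is None:
                width = row.size
            elif row.size != width:
                raise ParseError(
                    f"{path}:{lineno}: expected {width} columns, found {row.size}"
                )
            if not np.all(np.isfinite(row)):
                raise ParseError(f"{path}:{lineno}: non-finite value")
            rows.append(row)
    if not rows:
        raise ParseError(f"{path}: empty file")
    data = np.vstack(rows)
    T = data.shape[0]
    if T % n_runs != 0:
        raise ParseError(f"{path}: {T} timepoints not divisible into {n_runs} equal runs")
    boundaries = [r * (T // n_runs) for r in range(n_runs)]
    return NodeTimeSeriesSet(
        subject_id=subject_id or path.stem,
        data=data,
        run_boundaries=boundaries,
        tr_seconds=tr_seconds,
    )


def write_node_timeseries(ts: NodeTimeSeriesSet, path: str | Path, fmt: str = "%.6f") -> None:
    np.savetxt(path, ts.data, fmt=fmt)


def write_cohort(config, out_dir: str | Path) -> pd.DataFrame:
    """Materialize a synthetic cohort on disk.

    Writes ``phenotypes.csv``, one ``<subject>.txt`` node-time-series file per
    subject, ``manifest.csv`` (subject_id -> relative path), and
    ``cohort_config.yaml`` echoing every default. Returns the manifest frame.
    """
    from .config import cohort_config_to_dict
    from .synthetic import simulate_node_timeseries, simulate_phenotypes

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phen = simulate_phenotypes(config)
    phen.to_csv(out_dir / "phenotypes.csv")
    records = []
    for subject, ts in simulate_node_timeseries(config, phen).items():
        rel = f"timeseries/{subject}.txt"
        (out_dir / "timeseries").mkdir(exist_ok=True)
        write_node_timeseries(ts, out_dir / rel)
        records.append({"subject_id": subject, "path": rel})
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    import yaml

    (out_dir / "cohort_config.yaml").write_text(
        yaml.safe_dump(cohort_config_to_dict(config), sort_keys=False)
    )
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    manifest = pd.read_csv(path)
    if not {"subject_id", "path"} <= set(manifest.columns):
        raise ParseError(f"{path}: manifest needs 'subject_id' and 'path' columns")
    return manifest


def write_dcc_params(dcc_list: list[DccSeries], path: str | Path) -> None:
    """JSON sidecar of fitted DCC parameters and convergence flags (1-based pairs)."""
    payload = [
        {
            "node_i": d.pair[0] + 1,
            "node_j": d.pair[1] + 1,
            "a": d.a,
            "b": d.b,
            "loglik": None if np.isnan(d.loglik) else d.loglik,
            "converged": bool(d.converged),
        }
        for d in dcc_list
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def write_dcc_series(dcc_list: list[DccSeries], path: str | Path) -> None:
    """Long-format CSV (t, node_i, node_j, rho) of all conditional-correlation paths."""
    frames = []
    for d in dcc_list:
        frames.append(
            pd.DataFrame(
                {
                    "t": np.arange(d.rho.size),
                    "node_i": d.pair[0] + 1,
                    "node_j": d.pair[1] + 1,
                    "rho": d.rho,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def write_excursion_diagnostics(dcc_list: list[DccSeries], path: str | Path) -> None:
    """JSON dump of each pair's excursion set (median, crossings, tau/h list)."""
    from .tindex import find_excursions

    payload = []
    for d in dcc_list:
        exc = find_excursions(d.rho) if d.rho.size >= 3 else None
        payload.append(
            {
                "node_i": d.pair[0] + 1,
                "node_j": d.pair[1] + 1,
                "median": None if exc is None else exc.median_value,
                "n_excursions": 0 if exc is None else exc.N,
                "crossings": [] if exc is None else exc.crossings,
                "excursions": []
                if exc is None
                else [{"tau": e.tau, "h": e.h, "direction": e.direction} for e in exc.excursions],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=1))


def write_tindex_table(table: pd.DataFrame, wide_path: str | Path, long_path: str | Path | None = None) -> None:
    """Wide CSV (subject rows, ``i_j`` columns) and optional long CSV.

    Values are written at full precision so the table round-trips exactly.
    """
    table.to_csv(wide_path)
    if long_path is not None:
        long = table.reset_index().melt(
            id_vars="subject_id", var_name="connection", value_name="tindex"
        )
        ij = long["connection"].str.split("_", expand=True).astype(int)
        long["node_i"], long["node_j"] = ij[0], ij[1]
        long[["subject_id", "node_i", "node_j", "tindex"]].to_csv(long_path, index=False)


def read_tindex_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="subject_id")
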