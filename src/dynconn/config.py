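"""Run configuration: every stage parameter with an echoed default, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .synthetic import CohortConfig, DynamicsSpec, PlantedEffect

__all__ = [
    "RunConfig",
    "load_run_config",
    "save_run_config",
    "config_hash",
    "cohort_config_to_dict",
    "cohort_config_from_dict",
]


@dataclass
class RunConfig:
    """Parameters of the full pipeline, one field per stage knob."""

    out_dir: str = "dynconn_out"
    #: directory containing manifest.csv + phenotypes.csv; None -> simulate
    input_dir: str | None = None
    cohort: CohortConfig | None = None
    seed: int = 0
    arima_order: tuple[int, int, int] = (1, 0, 1)
    arima_method: str = "statespace"
    n_restarts: int = 3
    time_unit: str = "timepoints"  # or "seconds"
    train_frac: float = 0.75
    match_alpha: float = 0.05
    max_resamples: int = 1000
    fdr_alpha: float = 0.05
    pooled_fdr: bool = False
    save_dcc_series: bool = False
    threads: int = 1
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.time_unit not in ("timepoints", "seconds"):
            raise ValueError("time_unit must be 'timepoints' or 'seconds'")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must lie in (0, 1)")
        if self.input_dir is None and self.cohort is None:
            raise ValueError("either input_dir or a cohort config is required")


def cohort_config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["dynamic_pairs"] = {
        f"{i}_{j}": asdict(spec) if isinstance(spec, DynamicsSpec) else spec
        for (i, j), spec in config.dynamic_pairs.items()
    }
    d["stationary_pairs"] = {f"{i}_{j}": r for (i, j), r in config.stationary_pairs.items()}
    d["effect_map"] = [asdict(e) | {"pair": list(e.pair)} for e in config.effect_map]
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if d.get("dynamic_pairs") is not None:
        d["dynamic_pairs"] = {
            tuple(int(v) for v in k.split("_")): DynamicsSpec(**spec)
            for k, spec in d["dynamic_pairs"].items()
        }
    if d.get("stationary_pairs") is not None:
        d["stationary_pairs"] = {
            tuple(int(v) for v in k.split("_")): float(r)
            for k, r in d["stationary_pairs"].items()
        }
    d["effect_map"] = [
        PlantedEffect(
            trait=e["trait"], pair=tuple(e["pair"]), magnitude=e["magnitude"], sign=e.get("sign", -1)
        )
        for e in d.get("effect_map", [])
    ]
    if d.get("node_garch") is not None:
        d["node_garch"] = tuple(d["node_garch"])
    d["trait_params"] = {k: tuple(v) for k, v in d.get("trait_params", {}).items()} or None
    d["covariate_params"] = {k: tuple(v) for k, v in d.get("covariate_params", {}).items()} or None
    for key in ("trait_params", "covariate_params"):
        if d[key] is None:
            d.pop(key)
    return CohortConfig(**d)


def _run_config_to_dict(config: RunConfig) -> dict:
    d = {f.name: getattr(config, f.name) for f in fields(RunConfig)}
    d["arima_order"] = list(config.arima_order)
    d["cohort"] = cohort_config_to_dict(config.cohort) if config.cohort is not None else None
    return d


def save_run_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_run_config_to_dict(config), sort_keys=False))


def load_run_config(path: str | Path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    if d.get("cohort") is not None:
        d["cohort"] = cohort_config_from_dict(d["cohort"])
    if d.get("arima_order") is not None:
        d["arima_order"] = tuple(d["arima_order"])
    return RunConfig(**d)


def config_hash(config: RunConfig) -> str:
    """Short stable digest identifying a run configuration."""
    payload = json.dumps(_run_config_to_dict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
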