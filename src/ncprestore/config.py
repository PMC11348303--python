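"""Run configuration: YAML-backed settings for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .landscape import GeneratorConfig
from .sweep import PLAN_NAMES

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a full run needs, with the analysis' standard defaults."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    plans: tuple[str, ...] = PLAN_NAMES
    increments: int = 100
    decision_mode: str = "proportional"
    weight_mode: str = "group-equal"
    horizon_years: float = 30.0
    rural_weight: float = 1.0
    urban_weight: float = 0.2
    min_additional_aoh_km2: float = 0.0
    inclusion_threshold: float = 0.5
    cessation_tol: float = 1e-6
    #: equity reports at these budget percentages
    equity_budgets_pct: tuple[float, ...] = (5.0, 10.0, 17.0, 25.0, 50.0, 75.0, 100.0)
    seed: int = 0

    def validate(self) -> None:
        self.generator.validate()
        unknown = set(self.plans) - set(PLAN_NAMES)
        if unknown:
            raise ValueError(f"unknown plans: {sorted(unknown)}")
        if self.increments < 1:
            raise ValueError("increments must be >= 1")
        if self.decision_mode not in ("proportional", "binary"):
            raise ValueError(f"unknown decision_mode {self.decision_mode!r}")
        if self.weight_mode not in ("group-equal", "feature-equal"):
            raise ValueError(f"unknown weight_mode {self.weight_mode!r}")
        if not 0.0 <= self.inclusion_threshold <= 1.0:
            raise ValueError("inclusion_threshold must lie in [0, 1]")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from a YAML file plus overrides; unknown keys are
    rejected by name."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data.update(overrides)
    gen_data = data.pop("generator", {}) or {}
    gen_keys = {f.name for f in fields(GeneratorConfig)}
    bad = set(gen_data) - gen_keys
    if bad:
        raise ValueError(f"invalid generator config keys: {sorted(bad)}")
    run_keys = {f.name for f in fields(RunConfig)} - {"generator"}
    bad = set(data) - run_keys
    if bad:
        raise ValueError(f"invalid config keys: {sorted(bad)}")
    for tup_key in ("grid_shape", "people_totals", "rural_beta",
                    "elevation_range_m", "species_range_cells"):
        if tup_key in gen_data and isinstance(gen_data[tup_key], list):
            gen_data[tup_key] = tuple(gen_data[tup_key])
    for tup_key in ("plans", "equity_budgets_pct"):
        if tup_key in data and isinstance(data[tup_key], list):
            data[tup_key] = tuple(data[tup_key])
    cfg = RunConfig(generator=GeneratorConfig(**gen_data), **data)
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full configuration (for manifests/logs)."""
    blob = yaml.safe_dump(asdict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
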