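"""End-to-end pipeline: generate → assemble features → sweep → reports."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .config import RunConfig, config_hash
from .equity import EquityReport, equity_report, national_average
from .landscape import Landscape, SpeciesSpec, generate_landscape, generate_species
from .ncp import (
    NCPFeature,
    SpeciesTargetRecord,
    climate_feature,
    societal_feature,
    species_features,
    species_target_records,
)
from .sweep import PlanScheme, SweepResult, run_sweep

__all__ = ["PipelineResult", "assemble_features", "run_pipeline"]

log = logging.getLogger("ncprestore")


@dataclass
class PipelineResult:
    config: RunConfig
    landscape: Landscape
    species: list[SpeciesSpec]
    records: list[SpeciesTargetRecord]
    features: list[NCPFeature]
    sweeps: list[SweepResult]
    equity: list[EquityReport]

    @property
    def n_problems(self) -> int:
        return sum(len(s.solutions) for s in self.sweeps)


def assemble_features(landscape: Landscape, species: list[SpeciesSpec],
                      cfg: RunConfig
                      ) -> tuple[list[NCPFeature], list[SpeciesTargetRecord]]:
    """Climate + societal + per-species features from a landscape."""
    records, vectors = species_target_records(
        species, landscape, min_additional=cfg.min_additional_aoh_km2
    )
    features = [
        climate_feature(landscape, horizon_years=cfg.horizon_years),
        societal_feature(landscape, rural_weight=cfg.rural_weight,
                         urban_weight=cfg.urban_weight),
        *species_features(records, vectors),
    ]
    return features, records


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    cfg.validate()
    log.info("run config hash=%s seed=%d", config_hash(cfg), cfg.seed)
    landscape = generate_landscape(cfg.generator, cfg.seed)
    species = generate_species(
        landscape, cfg.generator.n_species, cfg.seed + 1,
        range_cells=cfg.generator.species_range_cells,
        viable_share=cfg.generator.species_viable_share,
    )
    features, records = assemble_features(landscape, species, cfg)
    plans = [PlanScheme(name, weight_mode=cfg.weight_mode) for name in cfg.plans]
    sweeps = run_sweep(landscape, features, plans,
                       increments=cfg.increments, decision_mode=cfg.decision_mode)
    for s in sweeps:
        log.info("plan=%s cessation=%s final objective=%.3g",
                 s.plan.name, s.cessation_budget_pct, s.objectives[-1])
    bio = next((s for s in sweeps if s.plan.name == "biodiversity-centric"), None)
    cessation = bio.cessation_budget_pct if bio is not None else None
    equity = equity_report(sweeps, landscape, list(cfg.equity_budgets_pct),
                           cessation_budget_pct=cessation)
    nat_d, nat_w = national_average(landscape)
    log.info("national means: disadvantaged=%.4f women=%.4f", nat_d, nat_w)
    return PipelineResult(
        config=cfg,
        landscape=landscape,
        species=species,
        records=records,
        features=features,
        sweeps=sweeps,
        equity=equity,
    )
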