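"""Assembly of the three NCP feature sets.

Climate NCP is the carbon a unit would accumulate over the first 30 years
of natural forest regrowth; societal NCP is the average number of
forest-reliant people across three needs (livelihoods, energy, housing)
with a rural/urban reliance weighting; biodiversity NCP is one feature per
species whose target is the Area-of-Habitat (AOH) restoration target from
an IUCN-style area-based protocol:

* both potential and current AOH below 2,200 km² — the preliminary target
  is the potential AOH itself;
* otherwise — ``min(max(2200, 0.8 * potential_aoh), 1e6)`` km².

Current AOH is the potential AOH lying outside the restoration mask; the
restoration target is the preliminary target minus current AOH, floored at
zero.

Units: restorable area in ha, AOH and species targets in km², carbon in tC,
people in persons.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .landscape import KM2_PER_HA, Landscape, SpeciesSpec

__all__ = [
    "NCPFeature",
    "SpeciesTargetRecord",
    "compute_potential_aoh",
    "preliminary_target",
    "restoration_target",
    "select_species_subset",
    "species_target_records",
    "climate_feature",
    "societal_feature",
    "species_features",
]

AOH_FLOOR_KM2 = 2200.0
AOH_CAP_KM2 = 1e6


@dataclass
class NCPFeature:
    """One optimization feature j: contributions r_ij, target t_j, weight w_j."""

    feature_id: str
    kind: str  # "climate" | "species" | "societal"
    contributions: np.ndarray
    target: float
    weight: float = 0.0
    degenerate: bool = False  # all-zero contribution vector

    def __post_init__(self) -> None:
        if self.kind not in ("climate", "species", "societal"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if np.any(self.contributions < 0):
            raise ValueError("contributions must be >= 0")
        if self.target < 0:
            raise ValueError("target must be >= 0")
        if self.weight < 0:
            raise ValueError("weight must be >= 0")

    @property
    def max_deliverable(self) -> float:
        return float(self.contributions.sum())


@dataclass(frozen=True)
class SpeciesTargetRecord:
    species_id: str
    potential_aoh: float  # km²
    current_aoh: float  # km²
    preliminary_target: float  # km²
    restoration_target: float  # km²
    in_subset: bool = False


def compute_potential_aoh(species: SpeciesSpec, landscape: Landscape
                          ) -> tuple[float, float, np.ndarray]:
    """Potential AOH split into in-restoration and outside components.

    A cell contributes iff it lies in the species range AND its habitat
    class is suitable AND its elevation is within the species' limits. The
    in-restoration part of a qualifying cell is its restorable area; the
    rest of the cell is current (outside) habitat. Returns
    ``(aoh_in_restoration_km2, aoh_outside_km2, per_unit_aoh_km2)`` where
    the vector holds the in-restoration contribution of every unit.
    """
    n = landscape.n_units
    per_unit = np.zeros(n)
    idx = np.fromiter(species.range_units, dtype=int)
    if idx.size == 0:
        return 0.0, 0.0, per_unit
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError("species range extends outside the grid")
    ok_hab = np.isin(landscape.habitat_class[idx], list(species.habitat_classes))
    elev = landscape.elevation[idx]
    ok = ok_hab & (elev >= species.elev_min) & (elev <= species.elev_max)
    good = idx[ok]
    per_unit[good] = landscape.restorable_area[good] * KM2_PER_HA
    outside = float(
        ((landscape.cell_area_ha - landscape.restorable_area[good]) * KM2_PER_HA).sum()
    )
    return float(per_unit.sum()), outside, per_unit


def preliminary_target(potential_aoh: float, current_aoh: float) -> float:
    """Preliminary AOH target (km²) from the area-based protocol."""
    if potential_aoh < 0 or current_aoh < 0:
        raise ValueError("AOH inputs must be >= 0")
    if potential_aoh < AOH_FLOOR_KM2 and current_aoh < AOH_FLOOR_KM2:
        return potential_aoh
    return min(max(AOH_FLOOR_KM2, 0.8 * potential_aoh), AOH_CAP_KM2)


def restoration_target(preliminary: float, current_aoh: float) -> float:
    """Habitat still to be restored: preliminary minus current, floored at 0."""
    if preliminary < 0 or current_aoh < 0:
        raise ValueError("inputs must be >= 0")
    return max(0.0, preliminary - current_aoh)


def species_target_records(species: list[SpeciesSpec], landscape: Landscape,
                           min_additional: float = 0.0
                           ) -> tuple[list[SpeciesTargetRecord], dict[str, np.ndarray]]:
    """Run the target-setting protocol for every species.

    Returns the records (with subset membership) and the per-unit
    in-restoration AOH vector for each species.
    """
    records, vectors = [], {}
    for sp in species:
        aoh_in, aoh_out, per_unit = compute_potential_aoh(sp, landscape)
        potential = aoh_in + aoh_out
        prelim = preliminary_target(potential, aoh_out)
        target = restoration_target(prelim, aoh_out)
        records.append(
            SpeciesTargetRecord(
                species_id=sp.species_id,
                potential_aoh=potential,
                current_aoh=aoh_out,
                preliminary_target=prelim,
                restoration_target=target,
            )
        )
        vectors[sp.species_id] = per_unit
    return select_species_subset(records, min_additional), vectors


def select_species_subset(records: list[SpeciesTargetRecord],
                          min_additional: float = 0.0) -> list[SpeciesTargetRecord]:
    """Flag the species for which restoration creates additional habitat
    beyond ``min_additional`` km² (default: any positive amount)."""
    return [
        replace(r, in_subset=bool(r.restoration_target > min_additional))
        for r in records
    ]


def climate_feature(landscape: Landscape, horizon_years: float = 30.0) -> NCPFeature:
    """Carbon (tC) accumulated over ``horizon_years`` of regrowth per unit.

    Units missing a carbon rate contribute zero but stay in the problem;
    the target is the maximum possible (the sum over all units).
    """
    rate = np.nan_to_num(landscape.carbon_rate, nan=0.0)
    r = rate * horizon_years * landscape.restorable_area
    return NCPFeature(
        feature_id="climate",
        kind="climate",
        contributions=r,
        target=float(r.sum()),
        degenerate=bool(r.sum() == 0.0),
    )


def societal_feature(landscape: Landscape, rural_weight: float = 1.0,
                     urban_weight: float = 0.2) -> NCPFeature:
    """Average forest-reliant people per unit across the three needs.

    Each need's count is weighted by the unit's rural/urban split
    (``rural_fraction * rural_weight + (1 - rural_fraction) * urban_weight``);
    units missing reliance data contribute zero but stay in the problem.
    """
    people = np.nan_to_num(landscape.people_by_need, nan=0.0)
    w = (landscape.rural_fraction * rural_weight
         + (1.0 - landscape.rural_fraction) * urban_weight)
    r = (people * w[:, None]).mean(axis=1)
    return NCPFeature(
        feature_id="societal",
        kind="societal",
        contributions=r,
        target=float(r.sum()),
        degenerate=bool(r.sum() == 0.0),
    )


def species_features(records: list[SpeciesTargetRecord],
                     per_unit_aoh: dict[str, np.ndarray]) -> list[NCPFeature]:
    """One feature per in-subset species; contributions are in-restoration
    AOH (km²) and the target is the restoration target.

    A species whose target exceeds its total deliverable AOH is kept — the
    shortfall variable absorbs the unreachable part.
    """
    out = []
    for rec in records:
        if not rec.in_subset:
            continue
        r = per_unit_aoh[rec.species_id]
        out.append(
            NCPFeature(
                feature_id=rec.species_id,
                kind="species",
                contributions=r,
                target=rec.restoration_target,
                degenerate=bool(r.sum() == 0.0),
            )
        )
    return out
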