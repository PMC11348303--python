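"""Readers and writers for landscapes, feature tables, and sweep outputs.

Continuous layers are written as ESRI ASCII grids (plain-text rasters,
one file per band); per-unit and per-species tables as CSV; run metadata
and the output manifest as YAML. A landscape round-trips losslessly
through ``write_landscape`` / ``read_landscape``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig, config_hash
from .equity import EquityReport
from .landscape import Landscape, SpeciesSpec, SubJurisdiction
from .ncp import SpeciesTargetRecord
from .sweep import SweepResult, accumulation_curves, selection_frequency

__all__ = [
    "write_ascii_grid",
    "read_ascii_grid",
    "write_landscape",
    "read_landscape",
    "write_species",
    "read_species",
    "write_species_targets",
    "write_curves",
    "write_frequency",
    "write_equity",
    "write_manifest",
]

log = logging.getLogger("ncprestore")

NODATA = -9999.0


def write_ascii_grid(path: Path, values: np.ndarray, grid_shape: tuple[int, int],
                     cell_side_km: float) -> None:
    """Write one flat per-unit layer as an ESRI ASCII grid (NaN -> nodata)."""
    rows, cols = grid_shape
    arr = np.where(np.isnan(values), NODATA, values).reshape(rows, cols)
    header = (
        f"ncols {cols}\nnrows {rows}\nxllcorner 0.0\nyllcorner 0.0\n"
        f"cellsize {cell_side_km * 1000.0}\nNODATA_value {NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt="%.17g")


def read_ascii_grid(path: Path) -> tuple[np.ndarray, tuple[int, int], float]:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        arr = np.loadtxt(fh)
    arr = np.atleast_2d(arr)
    arr[arr == header["nodata_value"]] = np.nan
    shape = (int(header["nrows"]), int(header["ncols"]))
    return arr.reshape(shape).ravel(), shape, header["cellsize"] / 1000.0


_LAYERS = ("restorable_area", "carbon_rate", "rural_fraction", "elevation")
_NEEDS = ("livelihoods", "energy", "housing")


def write_landscape(landscape: Landscape, outdir: Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    shape, side = landscape.grid_shape, landscape.cell_side_km
    for name in _LAYERS:
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, getattr(landscape, name), shape, side)
        written.append(p)
    for k, need in enumerate(_NEEDS):
        p = outdir / f"people_{need}.asc"
        write_ascii_grid(p, landscape.people_by_need[:, k], shape, side)
        written.append(p)
    for name in ("habitat_class", "subjur_id"):
        p = outdir / f"{name}.asc"
        write_ascii_grid(p, getattr(landscape, name).astype(float), shape, side)
        written.append(p)
    subs = pd.DataFrame(
        [
            {
                "subjur_id": s.subjur_id,
                "population": s.population,
                "frac_disadvantaged": s.frac_disadvantaged,
                "frac_women": s.frac_women,
            }
            for s in landscape.subjurisdictions
        ]
    )
    p = outdir / "subjurisdictions.csv"
    subs.to_csv(p, index=False, float_format="%.17g")
    written.append(p)
    meta = {"rng_seed": landscape.rng_seed, "cell_side_km": landscape.cell_side_km}
    p = outdir / "landscape.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(meta, fh)
    written.append(p)
    return written


def read_landscape(outdir: Path) -> Landscape:
    outdir = Path(outdir)
    layers = {}
    for name in _LAYERS + tuple(f"people_{n}" for n in _NEEDS) + ("habitat_class", "subjur_id"):
        layers[name], shape, side = read_ascii_grid(outdir / f"{name}.asc")
    subs_df = pd.read_csv(outdir / "subjurisdictions.csv", float_precision="round_trip")
    subs = [
        SubJurisdiction(int(r.subjur_id), float(r.population),
                        float(r.frac_disadvantaged), float(r.frac_women))
        for r in subs_df.itertuples()
    ]
    with open(outdir / "landscape.yaml") as fh:
        meta = yaml.safe_load(fh)
    people = np.stack([layers[f"people_{n}"] for n in _NEEDS], axis=1)
    return Landscape(
        grid_shape=shape,
        cell_side_km=float(meta["cell_side_km"]),
        restorable_area=layers["restorable_area"],
        carbon_rate=layers["carbon_rate"],
        people_by_need=people,
        rural_fraction=layers["rural_fraction"],
        elevation=layers["elevation"],
        habitat_class=np.nan_to_num(layers["habitat_class"]).astype(int),
        subjur_id=np.nan_to_num(layers["subjur_id"]).astype(int),
        subjurisdictions=subs,
        rng_seed=int(meta["rng_seed"]),
    )


def write_species(species: list[SpeciesSpec], landscape: Landscape,
                  outdir: Path) -> list[Path]:
    """Species table plus a run-length-free long-format range CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        [
            {
                "species_id": s.species_id,
                "habitat_classes": ";".join(str(c) for c in sorted(s.habitat_classes)),
                "elev_min": s.elev_min,
                "elev_max": s.elev_max,
            }
            for s in species
        ]
    )
    p1 = outdir / "species.csv"
    table.to_csv(p1, index=False, float_format="%.17g")
    ranges = pd.DataFrame(
        [
            {"species_id": s.species_id, "unit_id": u}
            for s in species
            for u in sorted(s.range_units)
        ]
    )
    p2 = outdir / "species_ranges.csv"
    ranges.to_csv(p2, index=False)
    return [p1, p2]


def read_species(outdir: Path) -> list[SpeciesSpec]:
    outdir = Path(outdir)
    table = pd.read_csv(outdir / "species.csv", float_precision="round_trip")
    ranges = pd.read_csv(outdir / "species_ranges.csv")
    grouped = ranges.groupby("species_id")["unit_id"].apply(list).to_dict()
    out = []
    for r in table.itertuples():
        out.append(
            SpeciesSpec(
                species_id=r.species_id,
                range_units=frozenset(int(u) for u in grouped.get(r.species_id, [])),
                habitat_classes=frozenset(
                    int(c) for c in str(r.habitat_classes).split(";")
                ),
                elev_min=float(r.elev_min),
                elev_max=float(r.elev_max),
            )
        )
    return out


def write_species_targets(records: list[SpeciesTargetRecord], path: Path) -> Path:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def write_curves(sweeps: list[SweepResult], path: Path) -> Path:
    """Tidy CSV: plan, budget_pct, ncp, delivered, fraction."""
    rows = []
    for sweep in sweeps:
        curves = accumulation_curves(sweep)
        for ncp in ("climate", "societal", "biodiversity"):
            for b, m, frac in zip(sweep.budgets_pct, sweep.metrics, curves[ncp]):
                rows.append(
                    {
                        "plan": sweep.plan.name,
                        "budget_pct": b,
                        "ncp": ncp,
                        "delivered": m[ncp],
                        "fraction": frac,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def write_frequency(sweeps: list[SweepResult], path: Path,
                    inclusion_threshold: float = 0.5) -> Path:
    rows = {}
    for sweep in sweeps:
        freq = selection_frequency(sweep, inclusion_threshold)
        rows[f"{sweep.plan.name}_count"] = freq["count"]
        rows[f"{sweep.plan.name}_fractional"] = freq["fractional"]
    df = pd.DataFrame(rows)
    df.insert(0, "unit_id", np.arange(len(df)))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def write_equity(reports: list[EquityReport], path: Path) -> Path:
    pd.DataFrame([r.__dict__ for r in reports]).to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def write_manifest(outdir: Path, cfg: RunConfig, files: list[Path]) -> Path:
    outdir = Path(outdir)
    manifest = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "weight_mode": cfg.weight_mode,
        "files": sorted(str(Path(f).relative_to(outdir)) for f in files),
    }
    p = outdir / "manifest.yaml"
    with open(p, "w") as fh:
        yaml.safe_dump(manifest, fh)
    return p


def manifest_complete(outdir: Path, cfg: RunConfig) -> bool:
    """True when a manifest with this config hash exists and every listed
    file is present (used by the resume flag)."""
    p = Path(outdir) / "manifest.yaml"
    if not p.exists():
        return False
    with open(p) as fh:
        manifest = yaml.safe_load(fh)
    if manifest.get("config_hash") != config_hash(cfg):
        return False
    return all((Path(outdir) / f).exists() for f in manifest.get("files", []))
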