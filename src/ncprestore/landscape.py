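"""Synthetic planning-unit landscapes.

Generates reproducible gridded landscapes with the statistical structure a
national restoration-prioritization analysis assumes: per-cell restorable
area, a spatially autocorrelated carbon-sequestration-rate field with a
configurable missing fraction, per-cell counts of forest-reliant people for
three needs (livelihoods, energy, housing) with a rural/urban split, an
elevation surface, categorical habitat classes, a nearest-centroid
tessellation of subjurisdictions carrying demographic fractions, and
species defined by a contiguous range, suitable habitat classes, and
elevational limits.

Missing data is an explicit sentinel (NaN), distinct from zero: a cell with
no carbon information still delivers the other NCP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "GeneratorConfig",
    "PlanningUnit",
    "SubJurisdiction",
    "SpeciesSpec",
    "Landscape",
    "generate_landscape",
    "calibrate_subjurisdictions",
    "generate_species",
    "smoothed_field",
]

#: km² per hectare; AOH and targets are kept in km², restorable area in ha.
KM2_PER_HA = 0.01


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic landscape generator.

    Defaults describe a 500 km × 500 km study region at 10-km resolution
    whose aggregate quantities (total restorable area, national reliance
    counts, demographic means) sit at the scale of a large national
    restoration program.
    """

    grid_shape: tuple[int, int] = (50, 50)
    cell_side_km: float = 10.0
    #: mean fraction of each cell that is restorable (degraded but forestable)
    restorable_mean_frac: float = 0.15
    #: Gaussian length scale, in cells, of the smoothed noise fields
    autocorr_length: float = 3.0
    #: lognormal parameters of the carbon accumulation rate (tC/ha/yr)
    carbon_rate_median: float = 2.0
    carbon_rate_sigma: float = 0.5
    #: fraction of units with no carbon-rate information
    missing_carbon_frac: float = 0.046
    #: fraction of units with no societal-reliance information
    missing_people_frac: float = 0.0015
    #: expected national totals of forest-reliant people per need
    #: (livelihoods, energy, housing), persons
    people_totals: tuple[float, float, float] = (280_000.0, 1_580_000.0, 480_000.0)
    #: Beta parameters of the per-unit rural population fraction
    rural_beta: tuple[float, float] = (6.5, 3.5)
    n_habitat_classes: int = 6
    elevation_range_m: tuple[float, float] = (0.0, 3000.0)
    n_subjurisdictions: int = 20
    #: population-weighted national means the demographic fractions are
    #: calibrated to (socioeconomically disadvantaged; women)
    disadvantaged_mean: float = 0.342
    women_mean: float = 0.489
    n_species: int = 56
    #: min/max species range size, in cells
    species_range_cells: tuple[int, int] = (6, 60)
    #: share of species guaranteed a nonzero potential AOH inside the
    #: restorable mask
    species_viable_share: float = 1.0

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError(f"grid_shape must be >= 1 in both dimensions, got {self.grid_shape}")
        for name in ("missing_carbon_frac", "missing_people_frac", "restorable_mean_frac",
                     "disadvantaged_mean", "women_mean", "species_viable_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.autocorr_length < 0:
            raise ValueError(f"autocorr_length must be >= 0, got {self.autocorr_length}")
        if self.n_subjurisdictions < 1:
            raise ValueError("n_subjurisdictions must be >= 1")
        if self.n_habitat_classes < 1:
            raise ValueError("n_habitat_classes must be >= 1")


@dataclass(frozen=True)
class SubJurisdiction:
    """Administrative polygon carrying demographic fractions."""

    subjur_id: int
    population: float
    frac_disadvantaged: float
    frac_women: float

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be >= 0")
        for name in ("frac_disadvantaged", "frac_women"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class PlanningUnit:
    """One grid cell that can be partially selected for restoration.

    ``carbon_rate`` and ``people_by_need`` are ``None`` when the layer has
    no data for the cell (distinct from zero).
    """

    unit_id: int
    row: int
    col: int
    restorable_area: float  # ha; the unit cost c_i
    carbon_rate: float | None  # tC/ha/yr
    people_by_need: tuple[float, float, float] | None  # persons
    rural_fraction: float
    subjur_id: int


@dataclass(frozen=True)
class SpeciesSpec:
    """A species: contiguous range, suitable habitat classes, elevation limits."""

    species_id: str
    range_units: frozenset[int]
    habitat_classes: frozenset[int]
    elev_min: float
    elev_max: float

    def __post_init__(self) -> None:
        if not self.range_units:
            raise ValueError("range_units must be nonempty")
        if self.elev_min > self.elev_max:
            raise ValueError("elev_min must be <= elev_max")


@dataclass
class Landscape:
    """A gridded study region held as flat per-unit arrays.

    Unit ``i`` sits at ``(i // cols, i % cols)``. NaN in ``carbon_rate``
    or in a row of ``people_by_need`` marks missing data.
    """

    grid_shape: tuple[int, int]
    cell_side_km: float
    restorable_area: np.ndarray  # (n,) ha
    carbon_rate: np.ndarray  # (n,) tC/ha/yr, NaN = missing
    people_by_need: np.ndarray  # (n, 3) persons, NaN row = missing
    rural_fraction: np.ndarray  # (n,) in [0, 1]
    elevation: np.ndarray  # (n,) m
    habitat_class: np.ndarray  # (n,) int labels
    subjur_id: np.ndarray  # (n,) int
    subjurisdictions: list[SubJurisdiction] = field(default_factory=list)
    rng_seed: int = 0

    @property
    def n_units(self) -> int:
        return self.restorable_area.size

    @property
    def cell_area_ha(self) -> float:
        return self.cell_side_km**2 * 100.0

    @property
    def cell_area_km2(self) -> float:
        return self.cell_side_km**2

    @property
    def total_restorable_area(self) -> float:
        """Σ c_i in ha — the 100% budget."""
        return float(self.restorable_area.sum())

    @property
    def units(self) -> list[PlanningUnit]:
        """Materialize the per-unit records (convenience view of the arrays)."""
        _, cols = self.grid_shape
        out = []
        for i in range(self.n_units):
            rate = self.carbon_rate[i]
            people = self.people_by_need[i]
            out.append(
                PlanningUnit(
                    unit_id=i,
                    row=i // cols,
                    col=i % cols,
                    restorable_area=float(self.restorable_area[i]),
                    carbon_rate=None if np.isnan(rate) else float(rate),
                    people_by_need=None if np.isnan(people).any() else tuple(float(p) for p in people),
                    rural_fraction=float(self.rural_fraction[i]),
                    subjur_id=int(self.subjur_id[i]),
                )
            )
        return out

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if np.any(self.restorable_area < 0) or np.any(self.restorable_area > self.cell_area_ha + 1e-9):
            raise ValueError("restorable_area must lie in [0, cell area]")
        rf = self.rural_fraction
        if np.any((rf < 0) | (rf > 1)):
            raise ValueError("rural_fraction must lie in [0, 1]")
        people = self.people_by_need
        present = ~np.isnan(people).any(axis=1)
        if np.any(people[present] < 0):
            raise ValueError("people counts must be >= 0 when present")
        known = {s.subjur_id for s in self.subjurisdictions}
        if not set(np.unique(self.subjur_id)) <= known:
            raise ValueError("every unit must belong to a known subjurisdiction")


def smoothed_field(rng: np.random.Generator, shape: tuple[int, int],
                   length: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise on a grid.

    ``length`` is the smoothing length scale in cell units; 0 returns the
    raw white noise (spatially independent values).
    """
    z = rng.standard_normal(shape)
    if length > 0:
        z = ndimage.gaussian_filter(z, sigma=length, mode="reflect")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def _choose_missing(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """Indices of exactly round(frac * n) units flagged as missing."""
    k = int(round(frac * n))
    if k == 0:
        return np.empty(0, dtype=int)
    return rng.choice(n, size=k, replace=False)


def generate_landscape(config: GeneratorConfig, seed: int) -> Landscape:
    """Generate a calibrated synthetic landscape, deterministic in ``seed``."""
    config.validate()
    rng = np.random.default_rng(seed)
    rows, cols = config.grid_shape
    n = rows * cols
    cell_area_ha = config.cell_side_km**2 * 100.0
    L = config.autocorr_length

    # Restorable area: smoothed field pushed through a logistic so the
    # restorable fraction clusters spatially, then scaled to the target mean.
    f = 1.0 / (1.0 + np.exp(-1.5 * smoothed_field(rng, (rows, cols), L).ravel()))
    mean_f = f.mean()
    if mean_f > 0:
        f = np.clip(f * (config.restorable_mean_frac / mean_f), 0.0, 1.0)
    restorable = f * cell_area_ha

    # Carbon rate: autocorrelated lognormal, then exact missing count.
    carbon = config.carbon_rate_median * np.exp(
        config.carbon_rate_sigma * smoothed_field(rng, (rows, cols), L).ravel()
    )
    carbon[_choose_missing(rng, n, config.missing_carbon_frac)] = np.nan

    # People per need: autocorrelated lognormal field per need scaled so the
    # expected national total matches the configured totals.
    people = np.empty((n, 3))
    for k, total in enumerate(config.people_totals):
        g = np.exp(0.8 * smoothed_field(rng, (rows, cols), L).ravel())
        people[:, k] = g * (total / g.sum())
    people[_choose_missing(rng, n, config.missing_people_frac), :] = np.nan

    a, b = config.rural_beta
    rural = rng.beta(a, b, size=n)

    lo, hi = config.elevation_range_m
    e = smoothed_field(rng, (rows, cols), L).ravel()
    e = (e - e.min()) / max(np.ptp(e), 1e-12)
    elevation = lo + e * (hi - lo)

    # Habitat classes: quantile bins of a smoothed field -> contiguous patches.
    h = smoothed_field(rng, (rows, cols), max(L, 1.0)).ravel()
    edges = np.quantile(h, np.linspace(0, 1, config.n_habitat_classes + 1)[1:-1])
    habitat = np.searchsorted(edges, h).astype(int)

    # Nearest-centroid tessellation into subjurisdictions.
    n_sub = min(config.n_subjurisdictions, n)
    centroids = rng.choice(n, size=n_sub, replace=False)
    cr, cc = centroids // cols, centroids % cols
    rr, uc = np.divmod(np.arange(n), cols)
    d2 = (rr[:, None] - cr[None, :]) ** 2 + (uc[:, None] - cc[None, :]) ** 2
    subjur = np.argmin(d2, axis=1)

    subs = [
        SubJurisdiction(
            subjur_id=j,
            population=float(rng.lognormal(mean=11.0, sigma=0.7)),
            frac_disadvantaged=float(rng.beta(2.0, 4.0)),
            frac_women=float(np.clip(rng.normal(0.489, 0.02), 0.0, 1.0)),
        )
        for j in range(n_sub)
    ]

    land = Landscape(
        grid_shape=config.grid_shape,
        cell_side_km=config.cell_side_km,
        restorable_area=restorable,
        carbon_rate=carbon,
        people_by_need=people,
        rural_fraction=rural,
        elevation=elevation,
        habitat_class=habitat,
        subjur_id=subjur,
        subjurisdictions=subs,
        rng_seed=int(seed),
    )
    land = calibrate_subjurisdictions(land, config.disadvantaged_mean, config.women_mean)
    land.validate()
    return land


def _shift_clip_calibrate(fracs: np.ndarray, weights: np.ndarray,
                          target: float) -> np.ndarray:
    """Shift-and-clip fractions so their weighted mean equals ``target``.

    The weighted mean of clip(fracs + d, 0, 1) is continuous and
    non-decreasing in d, spanning [0, 1] over d in [-1, 1]; a root-find on d
    places the mean on the target to ~1e-12.
    """
    w = weights / weights.sum()

    def mean_at(d: float) -> float:
        return float(np.clip(fracs + d, 0.0, 1.0) @ w)

    if abs(mean_at(0.0) - target) <= 1e-12:
        return fracs.copy()
    lo, hi = -1.0, 1.0
    if not (mean_at(lo) - target <= 0 <= mean_at(hi) - target):
        raise ValueError(
            f"calibration target {target} unreachable: fractions pinned at bounds"
        )
    d = optimize.brentq(lambda d: mean_at(d) - target, lo, hi, xtol=1e-15)
    out = np.clip(fracs + d, 0.0, 1.0)
    # polish the unclipped entries so the weighted mean is exact to <1e-12
    free = (out > 0.0) & (out < 1.0)
    if free.any():
        resid = target - float(out @ w)
        out[free] += resid / float(w[free].sum())
        out = np.clip(out, 0.0, 1.0)
    return out


def calibrate_subjurisdictions(landscape: Landscape,
                               target_disadvantaged_mean: float,
                               target_women_mean: float) -> Landscape:
    """Rescale demographic fractions so population-weighted national means
    hit the targets exactly (idempotent; raises if the target is pinned
    unreachable)."""
    for t in (target_disadvantaged_mean, target_women_mean):
        if not 0.0 < t < 1.0:
            raise ValueError(f"calibration target must lie in (0, 1), got {t}")
    subs = landscape.subjurisdictions
    pop = np.array([s.population for s in subs])
    if pop.sum() <= 0:
        raise ValueError("total population must be positive for calibration")
    dis = _shift_clip_calibrate(
        np.array([s.frac_disadvantaged for s in subs]), pop, target_disadvantaged_mean
    )
    wom = _shift_clip_calibrate(
        np.array([s.frac_women for s in subs]), pop, target_women_mean
    )
    new_subs = [
        replace(s, frac_disadvantaged=float(d), frac_women=float(w))
        for s, d, w in zip(subs, dis, wom)
    ]
    return replace_subjurisdictions(landscape, new_subs)


def replace_subjurisdictions(landscape: Landscape,
                             subs: list[SubJurisdiction]) -> Landscape:
    out = Landscape(
        grid_shape=landscape.grid_shape,
        cell_side_km=landscape.cell_side_km,
        restorable_area=landscape.restorable_area,
        carbon_rate=landscape.carbon_rate,
        people_by_need=landscape.people_by_need,
        rural_fraction=landscape.rural_fraction,
        elevation=landscape.elevation,
        habitat_class=landscape.habitat_class,
        subjur_id=landscape.subjur_id,
        subjurisdictions=subs,
        rng_seed=landscape.rng_seed,
    )
    return out


def _grow_blob(rng: np.random.Generator, shape: tuple[int, int],
               start: int, size: int) -> set[int]:
    """Contiguous range blob by randomized breadth-first growth."""
    rows, cols = shape
    blob = {start}
    frontier = [start]
    while len(blob) < size and frontier:
        i = frontier[rng.integers(len(frontier))]
        r, c = divmod(i, cols)
        nbrs = [
            nr * cols + nc
            for nr, nc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
            if 0 <= nr < rows and 0 <= nc < cols
        ]
        fresh = [j for j in nbrs if j not in blob]
        if not fresh:
            frontier.remove(i)
            continue
        j = fresh[rng.integers(len(fresh))]
        blob.add(j)
        frontier.append(j)
    return blob


def generate_species(landscape: Landscape, n_species: int, seed: int,
                     range_cells: tuple[int, int] = (6, 60),
                     viable_share: float = 1.0) -> list[SpeciesSpec]:
    """Draw species with contiguous ranges and habitat/elevation preferences.

    A ``viable_share`` fraction of the species is guaranteed a nonzero
    potential AOH inside the restorable mask (the preference draw is widened
    to cover at least one restorable range cell).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    n = landscape.n_units
    lo, hi = range_cells
    if lo > n:
        raise ValueError(f"species range size {lo} exceeds grid capacity {n}")
    rng = np.random.default_rng(seed)
    species = []
    for s in range(n_species):
        size = int(rng.integers(lo, min(hi, n) + 1))
        start = int(rng.integers(n))
        blob = _grow_blob(rng, landscape.grid_shape, start, size)
        idx = np.fromiter(blob, dtype=int)
        classes_in_range = np.unique(landscape.habitat_class[idx])
        k = int(rng.integers(1, len(classes_in_range) + 1))
        classes = set(rng.choice(classes_in_range, size=k, replace=False).tolist())
        elevs = landscape.elevation[idx]
        e_lo = float(np.quantile(elevs, rng.uniform(0.0, 0.3)))
        e_hi = float(np.quantile(elevs, rng.uniform(0.7, 1.0)))
        if s < round(viable_share * n_species):
            # widen preferences to cover the restorable range cell with the
            # largest restorable area, so potential AOH in the mask is > 0
            rest = landscape.restorable_area[idx]
            if rest.max() > 0:
                j = idx[int(np.argmax(rest))]
                classes.add(int(landscape.habitat_class[j]))
                e_lo = min(e_lo, float(landscape.elevation[j]))
                e_hi = max(e_hi, float(landscape.elevation[j]))
        species.append(
            SpeciesSpec(
                species_id=f"sp{s:03d}",
                range_units=frozenset(int(i) for i in blob),
                habitat_classes=frozenset(int(c) for c in classes),
                elev_min=e_lo,
                elev_max=e_hi,
            )
        )
    return species
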