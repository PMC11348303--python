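import numpy as np
import pytest

from ncprestore.landscape import (
    GeneratorConfig,
    Landscape,
    SubJurisdiction,
    generate_landscape,
)

SMALL_CONFIG = GeneratorConfig(
    grid_shape=(12, 12),
    n_subjurisdictions=6,
    n_species=8,
    species_range_cells=(4, 20),
)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return SMALL_CONFIG


@pytest.fixture(scope="session")
def small_landscape() -> Landscape:
    return generate_landscape(SMALL_CONFIG, seed=7)


def make_landscape(
    restorable,
    carbon_rate=None,
    people=None,
    rural=None,
    elevation=None,
    habitat=None,
    subjur_id=None,
    subjurisdictions=None,
    grid_shape=None,
    cell_side_km=10.0,
) -> Landscape:
    """Build a Landscape directly from arrays, filling benign defaults."""
    restorable = np.asarray(restorable, dtype=float)
    n = restorable.size
    if grid_shape is None:
        grid_shape = (1, n)
    if subjurisdictions is None:
        subjurisdictions = [SubJurisdiction(0, 1000.0, 0.3, 0.5)]
    return Landscape(
        grid_shape=grid_shape,
        cell_side_km=cell_side_km,
        restorable_area=restorable,
        carbon_rate=(np.full(n, 1.0) if carbon_rate is None
                     else np.asarray(carbon_rate, dtype=float)),
        people_by_need=(np.full((n, 3), 10.0) if people is None
                        else np.asarray(people, dtype=float)),
        rural_fraction=(np.full(n, 0.5) if rural is None
                        else np.asarray(rural, dtype=float)),
        elevation=(np.zeros(n) if elevation is None
                   else np.asarray(elevation, dtype=float)),
        habitat_class=(np.zeros(n, dtype=int) if habitat is None
                       else np.asarray(habitat, dtype=int)),
        subjur_id=(np.zeros(n, dtype=int) if subjur_id is None
                   else np.asarray(subjur_id, dtype=int)),
        subjurisdictions=subjurisdictions,
        rng_seed=0,
    )


def random_tiny_landscape(rng: np.random.Generator, shape=(8, 8)) -> Landscape:
    """Unstructured random landscape for brute-force oracle comparisons."""
    n = shape[0] * shape[1]
    cell_area_ha = 10.0**2 * 100.0
    return make_landscape(
        restorable=rng.uniform(0, cell_area_ha, n),
        carbon_rate=rng.uniform(0.5, 4.0, n),
        people=rng.uniform(0, 200, (n, 3)),
        rural=rng.uniform(0, 1, n),
        elevation=rng.uniform(0, 3000, n),
        habitat=rng.integers(0, 4, n),
        grid_shape=shape,
    )
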