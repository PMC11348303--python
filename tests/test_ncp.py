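"""NCP feature assembly: AOH filtering, target protocol, feature vectors."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ncprestore.landscape import SpeciesSpec
from ncprestore.ncp import (
    climate_feature,
    compute_potential_aoh,
    preliminary_target,
    restoration_target,
    select_species_subset,
    societal_feature,
    species_features,
    species_target_records,
    SpeciesTargetRecord,
)

from conftest import make_landscape, random_tiny_landscape


def brute_force_aoh(species, land):
    """Independent cell-by-cell triple-condition scan."""
    inside = outside = 0.0
    per_unit = np.zeros(land.n_units)
    for i in range(land.n_units):
        if i not in species.range_units:
            continue
        if int(land.habitat_class[i]) not in species.habitat_classes:
            continue
        if not (species.elev_min <= land.elevation[i] <= species.elev_max):
            continue
        inside += land.restorable_area[i] * 0.01
        outside += (land.cell_area_ha - land.restorable_area[i]) * 0.01
        per_unit[i] = land.restorable_area[i] * 0.01
    return inside, outside, per_unit


def test_aoh_triple_filter_worked_example():
    """4 range cells, habitat suitable in 3, elevation passes in 2, fully
    restorable 100 km² cells → 200 km² inside, 0 outside."""
    land = make_landscape(
        restorable=[10_000.0] * 4,
        habitat=[1, 1, 1, 2],
        elevation=[100.0, 200.0, 5000.0, 100.0],
    )
    sp = SpeciesSpec("sp", frozenset(range(4)), frozenset({1}), 0.0, 1000.0)
    inside, outside, per_unit = compute_potential_aoh(sp, land)
    assert inside == pytest.approx(200.0)
    assert outside == pytest.approx(0.0)
    assert np.count_nonzero(per_unit) == 2


def test_aoh_no_suitable_habitat_is_zero():
    land = make_landscape(restorable=[10_000.0] * 4, habitat=[1, 1, 1, 1])
    sp = SpeciesSpec("sp", frozenset(range(4)), frozenset({9}), 0.0, 1000.0)
    assert compute_potential_aoh(sp, land) == (0.0, 0.0, pytest.approx(np.zeros(4)))


def test_aoh_partial_restorable_splits_current_and_potential():
    land = make_landscape(restorable=[4_000.0], habitat=[0], elevation=[0.0])
    sp = SpeciesSpec("sp", frozenset({0}), frozenset({0}), -1.0, 1.0)
    inside, outside, _ = compute_potential_aoh(sp, land)
    assert inside == pytest.approx(40.0)
    assert outside == pytest.approx(60.0)  # rest of the 100 km² cell


def test_aoh_matches_brute_force_scan_on_random_landscapes():
    rng = np.random.default_rng(11)
    for _ in range(25):
        land = random_tiny_landscape(rng)
        units = rng.choice(land.n_units, size=rng.integers(1, 30), replace=False)
        sp = SpeciesSpec(
            "sp",
            frozenset(int(u) for u in units),
            frozenset(int(c) for c in rng.choice(4, size=rng.integers(1, 4), replace=False)),
            float(rng.uniform(0, 1500)),
            float(rng.uniform(1500, 3000)),
        )
        got = compute_potential_aoh(sp, land)
        want = brute_force_aoh(sp, land)
        assert got[0] == pytest.approx(want[0])
        assert got[1] == pytest.approx(want[1])
        assert got[2] == pytest.approx(want[2])


# --- target-setting protocol ----------------------------------------------


@pytest.mark.parametrize(
    "potential,current,expected",
    [
        (2_000.0, 1_000.0, 2_000.0),  # both below 2,200 → potential itself
        (10_000.0, 3_000.0, 8_000.0),  # 0.8 × potential between floor and cap
        (2_000_000.0, 3_000.0, 1_000_000.0),  # cap binds
        (2_500.0, 2_300.0, 2_200.0),  # floor binds (0.8 × 2,500 < 2,200)
        (2_000.0, 5_000.0, 2_200.0),  # current above threshold forces formula
        (0.0, 0.0, 0.0),
    ],
)
def test_preliminary_target_branches(potential, current, expected):
    assert preliminary_target(potential, current) == pytest.approx(expected)


def test_preliminary_target_rejects_negative():
    with pytest.raises(ValueError):
        preliminary_target(-1.0, 0.0)


@settings(max_examples=200, derandomize=True)
@given(
    potential=st.floats(0, 5e6, allow_nan=False),
    current=st.floats(0, 5e6, allow_nan=False),
)
def test_preliminary_target_bounds(potential, current):
    """Output is in [0, 1e6] and at least min(2,200, potential)."""
    t = preliminary_target(potential, current)
    assert 0.0 <= t <= 1e6
    assert t >= min(2_200.0, potential) - 1e-9


@pytest.mark.parametrize(
    "prelim,current,expected",
    [(8_000.0, 3_000.0, 5_000.0), (2_200.0, 2_300.0, 0.0), (123.0, 0.0, 123.0)],
)
def test_restoration_target(prelim, current, expected):
    assert restoration_target(prelim, current) == expected


def test_restoration_target_never_exceeds_in_restoration_aoh():
    """The protocol's target is always deliverable by the species' own
    restorable habitat (target ≤ Σ r_ij)."""
    rng = np.random.default_rng(5)
    for _ in range(500):
        inside = rng.uniform(0, 5000)
        current = rng.uniform(0, 5000)
        t = restoration_target(preliminary_target(inside + current, current), current)
        assert t <= inside + 1e-9


def _rec(sid, target):
    return SpeciesTargetRecord(sid, 100.0, 50.0, 60.0, target)


def test_subset_keeps_tiny_positive_targets():
    """Even a 0.79-ha (0.0079 km²) target counts as additional habitat."""
    recs = select_species_subset([_rec("a", 0.0), _rec("b", 0.0079)])
    assert [r.in_subset for r in recs] == [False, True]


def test_subset_empty_when_all_targets_zero():
    recs = select_species_subset([_rec("a", 0.0), _rec("b", 0.0)])
    assert not any(r.in_subset for r in recs)


# --- feature construction --------------------------------------------------


def test_climate_feature_linear_accrual():
    """2 tC/ha/yr on 100 restorable ha → 6,000 tC over 30 years."""
    land = make_landscape(restorable=[100.0], carbon_rate=[2.0])
    f = climate_feature(land, horizon_years=30.0)
    assert f.contributions[0] == pytest.approx(6_000.0)
    assert f.target == pytest.approx(6_000.0)


def test_climate_missing_rate_contributes_zero_but_stays():
    land = make_landscape(restorable=[100.0, 100.0], carbon_rate=[np.nan, 2.0])
    f = climate_feature(land)
    assert f.contributions[0] == 0.0
    assert f.contributions.size == 2
    assert f.target == pytest.approx(f.contributions.sum())


def test_climate_all_zero_is_degenerate():
    land = make_landscape(restorable=[100.0], carbon_rate=[0.0])
    f = climate_feature(land)
    assert f.degenerate and f.target == 0.0


def test_societal_plain_average():
    """Counts (30, 60, 90), fully rural with rural weight 1 → 60 persons."""
    land = make_landscape(restorable=[100.0], people=[[30.0, 60.0, 90.0]],
                          rural=[1.0])
    f = societal_feature(land, rural_weight=1.0, urban_weight=0.0)
    assert f.contributions[0] == pytest.approx(60.0)


def test_societal_rural_urban_weighting():
    land = make_landscape(restorable=[100.0], people=[[10.0, 10.0, 10.0]],
                          rural=[0.5])
    f = societal_feature(land, rural_weight=1.0, urban_weight=0.0)
    assert f.contributions[0] == pytest.approx(5.0)


def test_societal_missing_contributes_zero_but_stays():
    land = make_landscape(restorable=[100.0, 100.0],
                          people=[[np.nan] * 3, [30.0, 60.0, 90.0]], rural=[1.0, 1.0])
    f = societal_feature(land, rural_weight=1.0, urban_weight=0.0)
    assert f.contributions[0] == 0.0
    assert f.target == pytest.approx(60.0)


def test_species_features_assembly():
    recs = [SpeciesTargetRecord("a", 100.0, 60.0, 65.0, 25.0, in_subset=True)]
    vecs = {"a": np.full(4, 10.0)}
    feats = species_features(recs, vecs)
    assert len(feats) == 1
    assert feats[0].max_deliverable == pytest.approx(40.0)
    assert feats[0].target == 25.0
    assert species_features([], {}) == []


def test_climate_societal_target_equals_total(small_landscape):
    for f in (climate_feature(small_landscape), societal_feature(small_landscape)):
        assert f.target == f.contributions.sum()  # exact, not approx


def test_records_pipeline_counts(small_landscape):
    from ncprestore.landscape import generate_species

    species = generate_species(small_landscape, 5, seed=3)
    records, vectors = species_target_records(species, small_landscape)
    assert len(records) == 5 and len(vectors) == 5
    for r in records:
        assert r.potential_aoh >= 0 and r.restoration_target <= r.preliminary_target
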