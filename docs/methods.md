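# Methods

## Problem statement

The package prioritizes where to restore forest within a fixed budget of
restorable area so as to deliver three classes of nature's contributions to
people (NCP). Each planning unit is a grid cell with a restorable area
*c_i* (ha) — its cost. Each NCP feature *j* has a per-unit contribution
vector *r_ij*, a target *t_j*, and a plan-dependent weight *w_j*. The
optimizer minimizes the weighted sum of proportional shortfalls
Σ_j w_j y_j / t_j subject to Σ_i x_i r_ij + y_j ≥ t_j for every feature,
the budget constraint Σ_i x_i c_i ≤ B, x_i ∈ [0, 1], y_j ≥ 0.

The decision variable is proportional by default: restoring 40% of a unit
delivers 40% of each of its contributions. This makes the core problem a
linear program. A binary mode (whole-cell decisions, a MILP) is kept for
oracle verification and for users who want all-or-nothing plans. Both are
solved with the HiGHS solver through `scipy.optimize.linprog` /
`scipy.optimize.milp`, which is deterministic for a fixed input; residual
degeneracy among equally good solutions is resolved by input ordering.
Reported shortfalls are always recomputed tight, y_j = max(0, t_j −
Σ_i x_i r_ij), so they do not inherit solver slack.

Features with t_j = 0 are dropped from the objective (a zero target is
trivially met, and the proportional shortfall would be 0/0).

## NCP features

**Climate.** r_i = (carbon rate, tC/ha/yr) × 30 y × (restorable area, ha).
The 30-year accrual is linear in the annual rate; no saturation curve is
applied. The target is the maximum deliverable, Σ_i r_i, so the climate
shortfall at budget B measures the distance from the best possible
outcome. Units with a missing carbon rate contribute zero carbon but stay
in the problem — they still carry species habitat and people.

**Societal.** Each unit carries counts of people reliant on forests for
three needs (livelihoods, energy, housing). Each count is scaled by a
rural/urban reliance weight, rural_fraction × w_rural + (1 −
rural_fraction) × w_urban, and r_i is the mean of the three weighted
counts. Defaults w_rural = 1.0, w_urban = 0.2 encode the assumption that
forest reliance for basic needs is predominantly rural; both weights are
config-exposed because no authoritative split is available. The target is
again the maximum deliverable. Units with missing reliance data contribute
zero but stay in the problem.

**Biodiversity.** One feature per species. A cell contributes potential
Area of Habitat (AOH) iff it lies in the species' range AND its habitat
class is suitable AND its elevation is within the species' limits. The
in-restoration part of a qualifying cell's AOH is proportional to its
restorable area (the rest of the cell is current habitat); this
interpretation — scaling AOH by the restorable fraction rather than
counting whole cells — is a deliberate design choice for partial overlap.
Current AOH is the potential AOH outside the restoration mask.

Targets follow an area-based protocol inspired by IUCN Red List
assessment thresholds:

| potential AOH | current AOH | preliminary target (km²) |
|---|---|---|
| < 2,200 | < 2,200 | potential AOH |
| otherwise | | min(max(2,200, 0.8 × potential AOH), 10⁶) |

The implementation branches only on "both below 2,200" versus "otherwise":
the remaining protocol rows share one formula, and inventing a separate
case for potential < 2,200 with current ≥ 2,200 would not change the
result (the formula returns the 2,200 floor there, and the restoration
target below clamps at zero). The restoration target is
max(0, preliminary − current AOH); negative differences are meaningless
areas. A consequence worth noting: the restoration target never exceeds
the species' deliverable in-restoration AOH, so every species target is
individually attainable at a sufficient budget (this is what makes the
biodiversity plan's cessation generic rather than incidental).

Species enter the optimization only if their restoration target exceeds a
configurable `min_additional` threshold, default 0 km² — any strictly
positive additional habitat counts, since real analyses of this kind keep
targets as small as fractions of a hectare.

## Plans and weights

Single-objective plans weight only their own NCP. For the integrated plan
"all NCP weighted equally" is ambiguous when one NCP group holds one
feature and another holds dozens of species: the default **group-equal**
mode gives each NCP group total weight 1 (each of N species gets 1/N), so
biodiversity cannot dominate by feature count; a **feature-equal** mode
(every feature weight 1) is provided and surfaced in run metadata. The
biodiversity metric reported from a solution is the proportion of species
whose target is met within a 1e-6 relative tolerance.

## Budget sweep and derived outputs

A sweep solves one problem per (plan, budget) at evenly spaced budgets
b/increments × Σ c_i, b = 1…increments; the standard design is 4 plans ×
100 increments = 400 problems. Budgets are measured in restorable area
(ha), not cell counts. Derived outputs:

- **Accumulation curves**: delivered fraction per NCP vs. budget (climate
  and societal normalized by their maximum deliverable; biodiversity is
  already a proportion). A zero maximum is reported as NaN, not 0/0.
- **Selection frequency**: per unit, the number of budgets at which
  x_i ≥ 0.5 (the threshold is configurable and has no canonical value for
  fractional decisions, so a thresholdless fractional sum Σ_b x_i is
  emitted alongside).
- **Cessation budget**: the smallest budget at which a plan's objective is
  ≤ 1e-6 — all its weighted targets met. The sweep continues past
  cessation (solves are cheap); the cessation budget is a flag, not a
  truncation. Nestedness of consecutive solutions is measured (Jaccard)
  but never asserted: independent LP solves do not guarantee nested
  priorities.

Each problem is independent and deterministic, so sweep results do not
depend on execution order.

## Equity accounting

Societal-NCP beneficiaries of a solution are Σ_i x_i r_i (societal);
beneficiaries are apportioned fractionally by x_i, consistent with the
proportional decision. Group counts weight each unit's delivery by its
subjurisdiction's fraction of socioeconomically disadvantaged people or of
women; the two fractions are treated as independent marginals (no joint
distribution is modeled). Reports compare beneficiary shares against the
population-weighted national means and are grouped by whether the budget
lies within the biodiversity plan's cessation budget — the grouping is
keyed on the detected cessation, not hard-coded.

## Synthetic landscape generator

The generator emulates the statistical structure of the national input
layers such an analysis uses, not any real geography:

- **Grid**: 50×50 cells of 10 km side (cell area 10,000 ha). All defaults
  configurable.
- **Spatial autocorrelation**: every continuous layer derives from
  Gaussian-kernel-smoothed white noise with a length scale in cell units
  (default 3 cells); length 0 yields independent values. This is the
  simplest controllable stand-in for clustered real layers (regional
  carbon hotspots, contiguous upland blocks).
- **Restorable area**: a logistic transform of a smoothed field scaled to
  a mean restorable fraction of 0.15 per cell — total ≈ 3.7–3.9 Mha, the
  magnitude of a large national restoration commitment.
- **Carbon rate**: lognormal with median 2 tC/ha/yr and σ = 0.5 on the
  smoothed field, the range typical of natural regrowth. Exactly
  round(0.046 × n) units are set missing (NaN).
- **People per need**: three autocorrelated lognormal fields scaled so the
  expected national totals are 0.28 M (livelihoods), 1.58 M (energy) and
  0.48 M (housing) persons; exactly round(0.0015 × n) units missing.
- **Rural fraction**: Beta(6.5, 3.5) per unit, mean 0.65 — the rural
  population share of a largely rural country. Exposed as a free per-unit
  fraction because no standard spatial definition of rural/urban reliance
  exists.
- **Habitat classes**: quantile bins of a smoothed field (6 classes),
  giving spatially contiguous habitat patches. **Elevation**: a smoothed
  field scaled to 0–3,000 m.
- **Subjurisdictions**: nearest-centroid tessellation around 20 random
  cells (one unit belongs to exactly one subjurisdiction — at 10-km cells
  the overlap a real administrative map would produce is immaterial).
  Populations are lognormal; demographic fractions are drawn from Beta /
  truncated-normal distributions and then **calibrated**: a shift of all
  fractions, clipped to [0, 1], is root-found so the population-weighted
  mean equals the target exactly (within 1e-9; defaults 34.2%
  disadvantaged, 48.9% women), followed by a polish step on the unclipped
  entries. Calibration is idempotent and fails loudly if every fraction is
  pinned at a bound.
- **Species** (default 56): contiguous range blobs grown by randomized
  breadth-first search (6–60 cells), habitat preferences sampled from
  classes present in the range, elevation limits from within-range
  quantiles. A configurable share of species (default all) is guaranteed
  nonzero potential AOH inside the restorable mask by widening preferences
  to cover the range cell with the largest restorable area. Species whose
  protocol target comes out zero (current AOH already above the floor) are
  excluded from the optimization subset, so the feature count can be below
  the species count.

What the generator does **not** emulate: real land-cover exclusion rules,
actual species range maps or habitat associations, migration to or
saturation of carbon accumulation, and any correlation between demographic
fractions and NCP layers (they are drawn independently, so synthetic
equity gaps arise only from spatial coincidence). Passing tests therefore
demonstrate the correctness and internal consistency of the machinery —
optimality, monotone accumulation, cessation, equity identities — not any
statement about a real landscape.

## Numerical choices

- Feasibility, target-met, and cessation tolerances: 1e-6 (relative where
  a scale exists). Calibration tolerance: 1e-9.
- Problem sizes in the test and acceptance runs (50×50 sweep; 15×15 and
  10×10 landscapes for the dominance/monotonicity batteries; 8×8 for
  brute-force comparisons) were chosen so the whole suite completes in a
  few minutes while exercising every code path at non-trivial scale.
- The brute-force oracles are independent of the LP path: exhaustive
  subset enumeration (binary, ≤ 12 units) and the greedy ratio fill, which
  is provably optimal for the single-feature fractional knapsack.
- Text-only I/O: ESRI ASCII grids for rasters, CSV for tables, YAML for
  config and manifests, all at full double precision (`%.17g`,
  `float_precision="round_trip"`), so landscapes round-trip losslessly.

## Known limitations

- No boundary-length penalties, connectivity constraints, or locked
  in/out units; cost is restorable area only.
- The proportional decision delivers contributions linearly within a cell;
  real habitat value may be nonlinear in restored fraction.
- Cross-plan dominance is guaranteed (and tested) on each plan's weighted
  objective; the met-species *count* is not an LP objective, so another
  plan can occasionally meet more species at a given budget even though it
  has a worse biodiversity objective.
- Equity results on synthetic landscapes reflect the generator's
  independence assumptions; with real data, covariance between reliance
  and disadvantage drives the interesting signal.
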