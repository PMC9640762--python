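# Methods

`implant_access` audits a health system's capacity to remove subdermal
contraceptive implants, in three stages: a rule-based facility readiness
classification, a referral-network construction and rationality audit, and
dual-mode travel-time accessibility modeling with a population overlay. This
note documents the models, their assumptions, the defaults, and what the
synthetic data can and cannot demonstrate.

## Readiness classification

Each surveyed facility is scored on three components, in the style of WHO
Service Availability and Readiness Assessments (SARA): **general service
readiness** (running water, decontamination buckets, safety boxes, soap, and
implant removals offered at least 5 days per week), **human resources** (at
least one provider trained in implant removal; for difficult removals also
at least one trained in ultrasound use, since non-palpable implants must be
localised by imaging), and **minimum equipment** observed on site. The
regular-removal equipment set is syringes, local anesthetic, sterile band
aids, scalpel with blade, curved and straight forceps, and sterile gauze or
(antiseptic and cotton balls); difficult removals additionally require
modified vasectomy forceps, an ultrasound machine, sterile towels, an
examination table, a sterile surgical drape, and a sterile equipment tray.

The classification is strictly conjunctive — no weighting or partial credit
— and yields one of three nested levels: `NOT_READY`, `REGULAR`,
`DIFFICULT`. Design choices worth noting:

* **Criteria are data, not code.** A declarative `CriteriaTable` (item lists
  plus one OR-of-ANDs clause) drives the evaluator and can be loaded from
  YAML/JSON (`docs/criteria_default.json` is the shipped default). The
  consumables clause is written as *sterile gauze, or (antiseptic and cotton
  balls)*; the alternative reading *antiseptic and (cotton or gauze)* is
  expressible in the same schema and selectable at run time.
* **The sterile equipment tray** is required for the difficult level even
  though summary tables typically omit its row.
* **Autoclaves and second trained providers** are reported as additional
  indicators but never affect the level: sterilisation can be organised by
  other means, and the survey instrument does not distinguish training for
  regular versus difficult removals (hence a single removal-training count).
* **Rounding.** Summary percentages are whole percent, rounded half away
  from zero (`28/39 → 72`, `23/26 → 88`); access-table proportions are one
  decimal, allocated by largest remainder so each column sums to exactly
  100.0.
* Unassessed facilities (known only as referral destinations) are kept in
  the dataset but excluded from every readiness denominator.

## Referral networks

Each facility names at most one referral destination, so the referral graph
is a functional digraph that decomposes into star networks around receiving
facilities. Roles are `RECEIVING` (in-degree ≥ 1, taking precedence when a
facility both refers and receives), `REFERRING`, and `STANDALONE`. Chains
are structurally allowed but reported as warnings (surveyed networks are
stars); cycles are errors.

The *rationality* audit asks whether the facilities where cases terminate —
receiving facilities plus standalone ones — are ready for the cases they
must absorb. Unassessed receiving facilities are reported as `UNKNOWN` and
excluded from ready-count denominators; they can be admitted to the
geographic model with an explicitly assumed level (`assumed_levels` /
`--assume ID=LEVEL`), defaulting to exclusion.

## Travel-time accessibility

One-way travel time to the nearest facility ready at the requested level,
with two sub-models chosen per geography. All coordinates are planar meters
in a projected CRS; distances are Euclidean (district-scale study areas).

**Urban (road-network) model.** Clients ride public transport: time from a
neighborhood center is a fixed wait (default 50 min) plus network
shortest-path distance at a single average speed (default 10 kph), i.e.
`minutes = 50 + 6 × km` at the defaults. Origins and facilities snap to the
nearest network node (ties break to the smallest node id). Each center's
time is applied to its whole Thiessen (Voronoi) polygon, and neighborhood
populations are assigned to the resulting band. The model deliberately
ignores walking to the stop and traffic heterogeneity — one wait, one speed.

**Rural (cost-surface) model.** Clients walk across land cover and switch
to motorized transport on reaching a road, so each raster cell carries a
traversal speed: the road-class speed where a road crosses the cell
(defaults 60/40/20/10 kph for primary/secondary/tertiary/track), otherwise
a land-cover walking speed (2.5/2.0/1.5/1.0 kph for grassland/shrubland/
forest/wetland). The defaults sit inside the conventional 10–60 kph and
1–2.5 kph envelopes; exact per-class values are configuration. Travel time
accumulates by multi-source Dijkstra on the 8-connected cell graph with
step cost `d · (t_a + t_b)/2`, where `d` is the center-to-center distance
(cell size, ×√2 diagonally) and `t_c` the cell's minutes-per-meter — the
standard GIS cost-distance semantics. No-data cells are impassable;
accumulation is uncapped. Facilities on impassable cells snap to the
nearest passable cell within 5 cells (configurable); farther is an error.

On a uniform surface the 8-connected grid overestimates Euclidean shortest
time by at most the octile factor ≈ 1.0824; the tests enforce
`D/v ≤ T ≤ 1.0824·D/v` for every cell, and cell-exact agreement with an
independent Dijkstra run over an explicitly materialized sparse graph
(`scipy.sparse.csgraph`) on random rasters.

**Banding and overlay.** Hourly bands are half-open `[60k, 60(k+1))` with
everything ≥ 3 h collapsed to `3+` — the half-open convention makes the
bands a true partition, with 60.0 min falling in `1-2`. Populations (women
of reproductive age) come from a raster aligned to the travel-time grid
(rural) or per-neighborhood counts (urban); band shares are percentages of
the reachable total. One-way times are reported; round-trip doubling is a
reporting decision left to the caller.

## Synthetic data

`build_paper_fixture()` is a deterministic 40-facility, two-district survey
(13 + 26 assessed facilities plus one unassessed referral hospital) whose
district-level component marginals, referral topology (star networks of 20,
7 and 4), and facility-type mix reproduce a published two-district
assessment exactly under the rounding rule. The marginals do not determine
the item-level joint distribution; the fixture freezes one feasible joint
assignment (e.g. the three facilities lacking running water are disjoint
from the five with equipment gaps, which the regular-readiness count
requires) and `verify_fixture()` re-derives every summary figure as a
guard. The fixture is also shipped as `fixtures/facilities.csv` (+
GeoJSON), kept in sync by a test.

The parameterized generators draw component outcomes independently at
configurable pass rates (`gen_facilities`), build clustered land cover by
quantile-slicing smoothed Gaussian noise with roads burned along grid lines
(`gen_rural_scenario`), and lay a square street grid with uniform
neighborhood centers and lognormal populations (`gen_urban_scenario`). All
are seeded and bit-reproducible, and population totals are conserved
exactly. They emulate the *shape* of the study inputs, not their content:
no real road topology, land cover, or census raster is mimicked, so
passing tests demonstrate correctness of the algorithms and bookkeeping,
not the published access percentages — which depend on the real geodata.
Test problem sizes (20×20–41×41 rasters, grids of a few hundred nodes,
10,000-facility calibration runs) were chosen to exercise every code path
at desk scale.

## Numerical and degenerate-input conventions

* Percent rounding: half away from zero (integers); largest-remainder
  allocation (one-decimal access shares).
* Snap ties (nodes equidistant from a point): smallest node id. Cell
  assignment ties on polygon boundaries: lowest polygon index.
* Empty networks, zero assessed facilities, zero total population, sources
  outside the raster, all-impassable surfaces, referral cycles, and a
  requested level with no ready facility are all explicit errors, never
  silently empty outputs.
* Unreachable locations carry NaN travel time, band `unreachable`, and are
  excluded from access-table totals.

## Limitations

The readiness scheme is binary per item and cannot express stock levels or
quality of care. The referral model is single-destination and static. The
urban model's single wait time exaggerates travel time for clients within
walking distance; the rural model ignores terrain slope, seasonal
passability, and transport availability. Raster I/O uses the plain-text
ESRI ASCII grid format with a JSON legend sidecar, and geometries use
GeoJSON; no CRS transformations are performed — all inputs must already
share one projected CRS and grid.
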