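"""Synthetic inputs: the two-district study fixture and seeded generators.

Two kinds of synthetic data live here:

* :func:`build_paper_fixture` — a deterministic 40-facility dataset (39
  assessed across urban Dakar Centre, n=13, and rural Kolda, n=26, plus one
  hospital known only as a referral destination). The item-level booleans
  are one feasible joint assignment consistent with the published
  district-level component marginals and the published referral topology
  (three star networks of 20, 7 and 4 facilities); the marginals do not
  determine the joint, so the assignment is fixed here once and guarded by
  :func:`verify_fixture`.

* Seeded generators for facility surveys (:func:`gen_facilities`) and small
  urban / rural geographies (:func:`gen_urban_scenario`,
  :func:`gen_rural_scenario`) so every pipeline stage can be exercised at
  arbitrary size without any real geodata. Same seed, same output,
  bit-for-bit.

The generated geographies are deliberately stylised — grid road networks,
smoothed-noise land cover, independent per-component failure draws — and do
not mimic real road topology or census surfaces.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import box

from .geoaccess import RoadNetwork, SpeedSchedule, UrbanModelConfig
from .rasters import Raster
from .survey_data import (
    EQUIPMENT_ITEMS,
    District,
    EquipmentChecklist,
    FacilityRecord,
    FacilityType,
    GeneralServiceProfile,
    StaffingProfile,
)

# ---------------------------------------------------------------------------
# the two-district study fixture
# ---------------------------------------------------------------------------

_REGULAR_ITEMS = (
    "syringes",
    "local_anesthetic",
    "sterile_band_aids",
    "scalpel_with_blade",
    "curved_forceps",
    "straight_forceps",
)
_DIFFICULT_ITEMS = (
    "vasectomy_forceps",
    "ultrasound_machine",
    "sterile_towels",
    "examination_table",
    "sterile_surgical_drape",
    "sterile_equipment_tray",
)


def _equipment(missing: Sequence[str] = (), autoclave: bool = True) -> EquipmentChecklist:
    values = {item: item not in missing for item in EQUIPMENT_ITEMS}
    return EquipmentChecklist(**values, autoclave=autoclave)


@dataclass(frozen=True)
class _Fac:
    """Compact fixture row before expansion to a FacilityRecord."""

    fid: str
    district: District
    ftype: FacilityType
    xy: tuple[float, float]
    water: bool = True
    n_ultra: int = 0
    missing: tuple[str, ...] = ()
    refers_to: str | None = None
    n_removal: int = 2
    autoclave: bool = True


def _expand(c: _Fac) -> FacilityRecord:
    return FacilityRecord(
        facility_id=c.fid,
        district=c.district,
        facility_type=c.ftype,
        location=c.xy,
        general=GeneralServiceProfile(
            running_water=c.water,
            decontamination_buckets=True,
            safety_boxes=True,
            soap=True,
            removal_days_per_week=5,
        ),
        staffing=StaffingProfile(
            n_trained_removal=c.n_removal, n_trained_ultrasound=c.n_ultra
        ),
        equipment=_equipment(c.missing, autoclave=c.autoclave),
        refers_to=c.refers_to,
        assessed=True,
    )


def build_paper_fixture() -> list[FacilityRecord]:
    """The deterministic two-district fixture (40 records, 39 assessed).

    Dakar Centre (D01-D13, 6 health centers + 7 health posts): two
    facilities ready for difficult removals (D01, D02), eight for regular
    only, three not ready. Kolda (K01-K26, 1 health center + 25 health
    posts): one difficult-ready health post (K01), seventeen regular-only,
    eight not ready — three lacking running water, five missing equipment,
    disjoint sets. K00 is the Kolda hospital that receives referrals but was
    never assessed. Referral links form three star networks: D03 (size 7),
    K00 (size 4) and K04 (size 20).
    """
    D, HP = District.DAKAR_CENTRE, FacilityType.HEALTH_POST
    HC1, HC2 = FacilityType.HEALTH_CENTER_I, FacilityType.HEALTH_CENTER_II
    K = District.KOLDA

    def dak(i):  # compact deterministic coordinates, meters
        return (500.0 * (i % 5), 400.0 * (i // 5))

    def kol(i):
        return (30000.0 + 2500.0 * (i % 6), 2000.0 * (i // 6))

    rows: list[_Fac] = [
        # --- Dakar Centre: difficult-ready health centers -----------------
        _Fac("D01", D, HC1, dak(1), n_ultra=1, refers_to="D03"),
        _Fac("D02", D, HC1, dak(2), n_ultra=1),
        # regular-only; D03 receives the Dakar network
        _Fac("D03", D, HC1, dak(3), n_ultra=1,
             missing=("sterile_surgical_drape",)),
        _Fac("D04", D, HC1, dak(4), n_ultra=1,
             missing=("sterile_surgical_drape",), refers_to="D03"),
        _Fac("D05", D, HC1, dak(5),
             missing=("sterile_surgical_drape",), refers_to="D03"),
        _Fac("D06", D, HP, dak(6),
             missing=("ultrasound_machine",), refers_to="D03"),
        _Fac("D07", D, HP, dak(7),
             missing=("ultrasound_machine",), refers_to="D03"),
        _Fac("D08", D, HP, dak(8),
             missing=("ultrasound_machine", "vasectomy_forceps"),
             refers_to="D03", n_removal=1, autoclave=False),
        _Fac("D09", D, HC1, dak(9),
             missing=("ultrasound_machine", "vasectomy_forceps")),
        _Fac("D10", D, HP, dak(10),
             missing=("ultrasound_machine", "vasectomy_forceps"),
             autoclave=False),
        # not ready: regular equipment gaps
        _Fac("D11", D, HP, dak(11), n_removal=1, autoclave=False,
             missing=("syringes", "sterile_band_aids", "scalpel_with_blade",
                      "curved_forceps", "ultrasound_machine",
                      "vasectomy_forceps", "sterile_towels",
                      "sterile_surgical_drape")),
        _Fac("D12", D, HP, dak(12), autoclave=False,
             missing=("syringes", "sterile_band_aids", "scalpel_with_blade",
                      "curved_forceps", "ultrasound_machine",
                      "vasectomy_forceps", "sterile_towels",
                      "sterile_surgical_drape")),
        _Fac("D13", D, HP, dak(13), autoclave=False,
             missing=("local_anesthetic", "straight_forceps",
                      "ultrasound_machine", "vasectomy_forceps",
                      "sterile_towels", "sterile_surgical_drape")),
    ]

    # --- Kolda ---------------------------------------------------------
    # K01: the lone difficult-ready facility, refers to the hospital K00.
    rows.append(_Fac("K01", K, HP, kol(1), n_ultra=1, refers_to="K00"))
    # K02, K03: ultrasound machine + trained staff but no vasectomy forceps.
    for i in (2, 3):
        rows.append(
            _Fac(f"K0{i}", K, HP, kol(i), n_ultra=1,
                 missing=("vasectomy_forceps", "sterile_surgical_drape"),
                 refers_to="K00")
        )
    # K04: the receiving health center, regular-only (no ultrasound).
    rows.append(_Fac("K04", K, HC2, kol(4), missing=("ultrasound_machine",)))
    # K05..K16: regular-only posts referring to K04.
    for i in range(5, 17):
        rows.append(
            _Fac(f"K{i:02d}", K, HP, kol(i),
                 missing=("ultrasound_machine",),
                 refers_to="K04")
        )
    # K17, K18: regular-only, standalone.
    rows.append(
        _Fac("K17", K, HP, kol(17), missing=("ultrasound_machine",),
             n_removal=1)
    )
    rows.append(
        _Fac("K18", K, HP, kol(18),
             missing=("ultrasound_machine", "vasectomy_forceps",
                      "sterile_surgical_drape"),
             n_removal=1, autoclave=False)
    )
    # K19..K21: no running water (equipment complete for regular).
    for i in (19, 20, 21):
        rows.append(
            _Fac(f"K{i}", K, HP, kol(i), water=False,
                 missing=("ultrasound_machine", "vasectomy_forceps",
                          "sterile_surgical_drape")
                 + (("sterile_towels",) if i >= 20 else ()),
                 refers_to="K04", n_removal=1, autoclave=False)
        )
    # K22..K26: regular-equipment gaps (disjoint from the water failures).
    gaps = {
        22: ("syringes", "scalpel_with_blade"),
        23: ("local_anesthetic",),
        24: ("local_anesthetic", "straight_forceps"),
        25: ("sterile_band_aids",),
        26: ("scalpel_with_blade",),
    }
    for i, gap in gaps.items():
        rows.append(
            _Fac(f"K{i}", K, HP, kol(i),
                 missing=gap + ("ultrasound_machine", "vasectomy_forceps",
                                "sterile_towels", "sterile_surgical_drape"),
                 refers_to="K04" if i <= 25 else None,
                 n_removal=1, autoclave=False)
        )

    records = [_expand(c) for c in rows]
    # the unassessed hospital: coordinates only, receives the K01-K03 links
    records.append(
        FacilityRecord(
            facility_id="K00",
            district=K,
            facility_type=FacilityType.HOSPITAL,
            location=(31000.0, 9000.0),
            assessed=False,
        )
    )
    return records


def verify_fixture(records: Sequence[FacilityRecord] | None = None) -> dict[str, bool]:
    """Self-check: the fixture reproduces every published summary figure.

    Returns a dict of named checks, all of which must be True; raises
    ``AssertionError`` on the first failure.
    """
    from .readiness import summarize_readiness
    from .referral import build_networks

    records = list(records) if records is not None else build_paper_fixture()
    summary = summarize_readiness(records)
    t = summary.table
    build = build_networks(records)
    sizes = sorted((n.size for n in build.networks), reverse=True)
    checks = {
        "n_assessed_39": summary.n_by_district["Total"] == 39,
        "regular_72": t.loc["Regular removals", "Total"] == 72,
        "difficult_8": t.loc["Difficult removals", "Total"] == 8,
        "general_92": t.loc["General service readiness", "Total"] == 92,
        "equip_regular_79": t.loc["Minimum equipment (regular)", "Total"] == 79,
        "equip_difficult_8": t.loc["Minimum equipment (difficult)", "Total"] == 8,
        "ultrasound_staff_18": t.loc[
            "Human resources: 1+ staff trained to use ultrasound", "Total"
        ] == 18,
        "ultrasound_machine_21": t.loc["Ultrasound", "Total"] == 21,
        "network_sizes_20_7_4": sizes == [20, 7, 4],
        "referring_28": build.role_counts()["REFERRING"] == 28,
        "standalone_9": build.role_counts()["STANDALONE"] == 9,
        "health_posts_82": (
            sum(
                1
                for f in records
                if f.assessed and f.facility_type == FacilityType.HEALTH_POST
            )
            == 32
        ),
    }
    for name, ok in checks.items():
        assert ok, f"fixture self-check failed: {name}"
    return checks


# ---------------------------------------------------------------------------
# parameterized survey generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentRates:
    """Per-component pass probabilities for the survey generator."""

    general: float = 0.9
    hr_regular: float = 1.0
    hr_ultrasound: float = 0.2
    equip_regular: float = 0.8
    equip_difficult_extra: float = 0.1

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate {name} must be in [0, 1], got {p}")

    @property
    def regular_composite(self) -> float:
        """P(level >= REGULAR) under independent component draws."""
        return self.general * self.hr_regular * self.equip_regular


def gen_facilities(
    n: int, rates: ComponentRates = ComponentRates(), seed: int | None = 0
) -> list[FacilityRecord]:
    """Draw ``n`` synthetic facilities with independent component outcomes.

    Each component passes with its configured probability; item-level
    booleans are then filled consistently with the drawn component status (a
    failing component has exactly one randomly chosen item missing). Seeded
    and deterministic.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        district = District.DAKAR_CENTRE if rng.random() < 0.4 else District.KOLDA
        general_pass = rng.random() < rates.general
        water = True
        days = int(rng.integers(5, 8))
        if not general_pass:
            if rng.random() < 0.5:
                water = False
            else:
                days = int(rng.integers(0, 5))
        missing: list[str] = []
        if rng.random() >= rates.equip_regular:
            missing.append(str(rng.choice(_REGULAR_ITEMS)))
        if rng.random() >= rates.equip_difficult_extra:
            missing.append(str(rng.choice(_DIFFICULT_ITEMS)))
        records.append(
            FacilityRecord(
                facility_id=f"S{i:05d}",
                district=district,
                facility_type=FacilityType.HEALTH_POST,
                location=(float(rng.uniform(0, 50_000)), float(rng.uniform(0, 50_000))),
                general=GeneralServiceProfile(
                    running_water=water,
                    decontamination_buckets=True,
                    safety_boxes=True,
                    soap=True,
                    removal_days_per_week=days,
                ),
                staffing=StaffingProfile(
                    n_trained_removal=int(rng.random() < rates.hr_regular),
                    n_trained_ultrasound=int(rng.random() < rates.hr_ultrasound),
                ),
                equipment=_equipment(missing, autoclave=bool(rng.random() < 0.64)),
                assessed=True,
            )
        )
    return records


# ---------------------------------------------------------------------------
# geographies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticGeoSpec:
    """Parameters for the synthetic urban / rural geographies.

    Rural: an ``n_cells`` x ``n_cells`` land-cover raster (classes drawn
    from ``surface_mixture`` with spatial clustering set by
    ``clustering_sigma`` cells), roads burned along grid lines every
    ``road_spacing_cells``, and a population raster summing exactly to
    ``population_total``. Urban: a square street grid of
    ``urban_grid_nodes`` x ``urban_grid_nodes`` nodes spaced
    ``urban_spacing_m`` apart with ``n_neighborhoods`` centers inside the
    bounding box.
    """

    n_cells: int = 60
    cell_size_m: float = 500.0
    surface_mixture: tuple[tuple[str, float], ...] = (
        ("grassland", 0.45),
        ("shrubland", 0.30),
        ("forest", 0.15),
        ("wetland", 0.10),
    )
    clustering_sigma: float = 3.0
    road_spacing_cells: int = 15
    road_classes: tuple[str, ...] = ("primary", "secondary")
    population_total: float = 100_000.0
    population_clustered: bool = True
    n_facilities: int = 3
    urban_grid_nodes: int = 12
    urban_spacing_m: float = 500.0
    n_neighborhoods: int = 425
    seed: int = 0


@dataclass
class RuralScenario:
    surface_raster: Raster
    road_raster: Raster
    population_raster: Raster
    facility_points: list[tuple[float, float]]
    schedule: SpeedSchedule


@dataclass
class UrbanScenario:
    network: RoadNetwork
    neighborhood_points: list[tuple[float, float]]
    boundary: object  # shapely Polygon
    neighborhood_population: np.ndarray
    facility_points: list[tuple[float, float]]
    config: UrbanModelConfig


def gen_rural_scenario(spec: SyntheticGeoSpec = SyntheticGeoSpec()) -> RuralScenario:
    """Aligned land-cover / road / population rasters plus facility points."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    names = [name for name, _ in spec.surface_mixture]
    weights = np.array([w for _, w in spec.surface_mixture], dtype=float)
    if n <= 0 or spec.population_total <= 0 or not math.isclose(weights.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("invalid geo spec (grid size, population, or mixture)")

    # clustered land cover: quantile-sliced smoothed noise
    fld = gaussian_filter(rng.standard_normal((n, n)), sigma=spec.clustering_sigma)
    edges = np.quantile(fld, np.cumsum(weights)[:-1])
    codes = np.digitize(fld, edges).astype(float)
    surface = Raster(
        codes, spec.cell_size_m, legend={i: nm for i, nm in enumerate(names)}
    )

    # roads along grid lines
    road = np.full((n, n), np.nan)
    for k, line in enumerate(range(spec.road_spacing_cells, n, spec.road_spacing_cells)):
        code = k % len(spec.road_classes)
        road[line, :] = code
        road[:, line] = code
    road_raster = Raster(
        road,
        spec.cell_size_m,
        legend={i: nm for i, nm in enumerate(spec.road_classes)},
    )

    # population, conserved exactly
    if spec.population_clustered:
        w = np.exp(gaussian_filter(rng.standard_normal((n, n)), sigma=spec.clustering_sigma) * 2)
    else:
        w = np.ones((n, n))
    pop = w * (spec.population_total / w.sum())
    pop_raster = Raster(pop, spec.cell_size_m)

    # facilities at random cells (every land-cover class is passable)
    cells = rng.choice(n * n, size=spec.n_facilities, replace=False)
    pts = [surface.index_to_point(int(c // n), int(c % n)) for c in cells]
    return RuralScenario(
        surface_raster=surface,
        road_raster=road_raster,
        population_raster=pop_raster,
        facility_points=pts,
        schedule=SpeedSchedule(),
    )


def gen_urban_scenario(spec: SyntheticGeoSpec = SyntheticGeoSpec()) -> UrbanScenario:
    """Street-grid network, neighborhood centers and populations, facilities."""
    if spec.n_neighborhoods <= 0:
        raise ValueError("n_neighborhoods must be positive")
    rng = np.random.default_rng(spec.seed)
    g, s = spec.urban_grid_nodes, spec.urban_spacing_m
    nodes = {
        f"n{i}_{j}": (i * s, j * s) for i, j in itertools.product(range(g), range(g))
    }
    edges = []
    for i, j in itertools.product(range(g), range(g)):
        if i + 1 < g:
            edges.append((f"n{i}_{j}", f"n{i + 1}_{j}", s, "street"))
        if j + 1 < g:
            edges.append((f"n{i}_{j}", f"n{i}_{j + 1}", s, "street"))
    net = RoadNetwork.from_edges(nodes, edges)
    extent = (g - 1) * s
    boundary = box(0.0, 0.0, extent, extent)
    pts = [
        (float(x), float(y))
        for x, y in zip(
            rng.uniform(0, extent, spec.n_neighborhoods),
            rng.uniform(0, extent, spec.n_neighborhoods),
        )
    ]
    pops = rng.lognormal(mean=6.0, sigma=0.8, size=spec.n_neighborhoods)
    node_ids = sorted(nodes)
    fac_nodes = rng.choice(len(node_ids), size=spec.n_facilities, replace=False)
    fac_pts = [nodes[node_ids[int(k)]] for k in fac_nodes]
    return UrbanScenario(
        network=net,
        neighborhood_points=pts,
        boundary=boundary,
        neighborhood_population=pops,
        facility_points=fac_pts,
        config=UrbanModelConfig(),
    )
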