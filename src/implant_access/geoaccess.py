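"""Travel-time accessibility to removal-ready facilities.

Two one-way travel-time models, reflecting how clients actually move in the
two study settings, feed a common population overlay:

* **Urban (road-network) model.** Clients take public transport along the
  road network. Travel time from a neighborhood center to the nearest ready
  facility is a fixed wait for pick-up plus network shortest-path distance
  at a single average speed. Each neighborhood center's time is applied to
  its whole Thiessen (Voronoi) polygon, and the neighborhood population is
  assigned to the resulting hourly band.

* **Rural (cost-surface) model.** Clients walk across land cover until they
  reach a road, then ride. Every grid cell carries a traversal speed (road
  class speed where a road is present, else a land-cover walking speed);
  travel time accumulates along least-cost paths from all ready facilities
  simultaneously (multi-source Dijkstra on the 8-connected cell graph, with
  the per-meter cost of a step averaged between the two cells it joins).
  Cell populations are then summed by hourly band.

Both models report one-way minutes; the hourly bands are half-open
[60k, 60(k+1)) with everything at three hours or more collapsed to "3+".
"""

from __future__ import annotations

import heapq
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import voronoi_diagram
from shapely.strtree import STRtree

from .rasters import Raster
from .readiness import Level, ReadinessResult
from .survey_data import FacilityRecord

SQRT2 = math.sqrt(2.0)

#: Hourly band labels, index = floor(minutes / 60) clipped to 3.
BAND_LABELS = ("0-1", "1-2", "2-3", "3+")
UNREACHABLE = "unreachable"


class NoReadyFacilityError(ValueError):
    """No facility is ready at the requested level."""


class ScheduleCoverageError(KeyError):
    """A raster class has no speed-schedule entry."""


# ---------------------------------------------------------------------------
# road network (urban model)
# ---------------------------------------------------------------------------

@dataclass
class RoadNetwork:
    """Undirected road graph; nodes carry planar coordinates in meters.

    Edge attribute ``length_m`` is the traversal length; ``road_class`` is
    carried through for reporting. Edge lengths are checked against node
    coordinates unless explicitly overridden.
    """

    graph: nx.Graph

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if d.get("length_m", 0) <= 0:
                raise ValueError(f"edge ({u}, {v}) must have positive length_m")

    @classmethod
    def from_edges(
        cls,
        nodes: Mapping[str, tuple[float, float]],
        edges: Sequence[tuple[str, str, float, str]],
        length_tolerance: float | None = 1e-6,
    ) -> "RoadNetwork":
        """Build from (node -> (x, y)) and (u, v, length_m, road_class) lists.

        With ``length_tolerance`` set (meters), each stated length must match
        the inter-node Euclidean distance to within the tolerance; pass
        ``None`` to accept lengths as-is (e.g. sinuous roads).
        """
        g = nx.Graph()
        for nid, (x, y) in nodes.items():
            g.add_node(nid, x=float(x), y=float(y))
        for u, v, length_m, road_class in edges:
            if length_tolerance is not None:
                dx = nodes[u][0] - nodes[v][0]
                dy = nodes[u][1] - nodes[v][1]
                euclid = math.hypot(dx, dy)
                if abs(euclid - length_m) > length_tolerance:
                    raise ValueError(
                        f"edge ({u}, {v}) length_m={length_m} inconsistent with "
                        f"node coordinates (Euclidean {euclid:.3f} m)"
                    )
            g.add_edge(u, v, length_m=float(length_m), road_class=road_class)
        return cls(graph=g)

    @classmethod
    def from_geojson(cls, path) -> "RoadNetwork":
        """Read LineString features (property ``road_class``); consecutive
        vertices become edges, vertices shared between lines become shared
        nodes."""
        import json as _json

        with open(path) as fh:
            gj = _json.load(fh)
        g = nx.Graph()

        def node_id(coord):
            return f"{coord[0]:.3f},{coord[1]:.3f}"

        for feat in gj["features"]:
            geom = feat["geometry"]
            if geom["type"] != "LineString":
                continue
            cls_name = feat.get("properties", {}).get("road_class", "unclassified")
            coords = geom["coordinates"]
            for a, b in zip(coords[:-1], coords[1:]):
                na, nb = node_id(a), node_id(b)
                g.add_node(na, x=float(a[0]), y=float(a[1]))
                g.add_node(nb, x=float(b[0]), y=float(b[1]))
                length = math.hypot(a[0] - b[0], a[1] - b[1])
                if length > 0:
                    g.add_edge(na, nb, length_m=length, road_class=cls_name)
        return cls(graph=g)

    def node_xy(self, nid) -> tuple[float, float]:
        d = self.graph.nodes[nid]
        return d["x"], d["y"]


@dataclass(frozen=True)
class UrbanModelConfig:
    """One wait time and one travel speed, applied uniformly."""

    wait_time_min: float = 50.0
    speed_kph: float = 10.0

    def __post_init__(self) -> None:
        if self.wait_time_min < 0:
            raise ValueError("wait_time_min must be >= 0")
        if self.speed_kph <= 0:
            raise ValueError("speed_kph must be > 0")


def snap_to_network(p: tuple[float, float], net: RoadNetwork):
    """Nearest node by Euclidean distance; ties break to the smallest node id."""
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot snap to an empty network")
    best = min(
        net.graph.nodes,
        key=lambda nid: (
            math.hypot(net.graph.nodes[nid]["x"] - p[0], net.graph.nodes[nid]["y"] - p[1]),
            str(nid),
        ),
    )
    return best


def urban_travel_time(
    origins: Sequence[tuple[float, float]],
    facilities: Sequence[tuple[float, float]],
    net: RoadNetwork,
    cfg: UrbanModelConfig = UrbanModelConfig(),
) -> np.ndarray:
    """One-way minutes from each origin to the nearest facility.

    minutes = wait_time + 60 * (network km to nearest facility) / speed_kph.
    Origins disconnected from every facility get NaN (with a warning).
    """
    if not facilities:
        raise ValueError("facilities must be non-empty")
    facility_nodes = {snap_to_network(p, net) for p in facilities}
    dist_m = nx.multi_source_dijkstra_path_length(
        net.graph, facility_nodes, weight="length_m"
    )
    minutes = np.full(len(origins), np.nan)
    for i, p in enumerate(origins):
        node = snap_to_network(p, net)
        if node in dist_m:
            minutes[i] = cfg.wait_time_min + 60.0 * (dist_m[node] / 1000.0) / cfg.speed_kph
        else:
            warnings.warn(
                f"origin {i} snapped to node {node!r} unreachable from every facility"
            )
    return minutes


def thiessen_polygons(
    points: Sequence[tuple[float, float]], boundary: Polygon
) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to ``boundary``, in point order.

    The cells partition the boundary: every interior location lands in the
    cell of its nearest seed. Duplicate points are an error.
    """
    pts = [Point(p) for p in points]
    if len({(p.x, p.y) for p in pts}) != len(pts):
        raise ValueError("duplicate points")
    if not any(boundary.intersects(p) for p in pts):
        raise ValueError("no point falls inside the boundary")
    if len(pts) == 1:
        return [Polygon(boundary)]
    cells = voronoi_diagram(MultiPoint(pts), envelope=boundary)
    tree = STRtree(list(cells.geoms))
    out: list[Polygon] = []
    for p in pts:
        idx = tree.query(p, predicate="intersects")
        if len(idx) == 0:  # pragma: no cover - seeds always lie in their cell
            raise RuntimeError(f"no Voronoi cell found for point {p}")
        cell = cells.geoms[int(idx[0])]
        out.append(cell.intersection(boundary))
    return out


# ---------------------------------------------------------------------------
# cost surface (rural model)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeedSchedule:
    """Traversal speed per road class and walking speed per surface class.

    Road speeds span roughly 10-60 kph by class; off-road walking speeds span
    1-2.5 kph by land cover. Every class present in the input rasters must
    have an entry.
    """

    road_kph: Mapping[str, float] = field(
        default_factory=lambda: {
            "primary": 60.0,
            "secondary": 40.0,
            "tertiary": 20.0,
            "track": 10.0,
        }
    )
    walk_kph: Mapping[str, float] = field(
        default_factory=lambda: {
            "grassland": 2.5,
            "shrubland": 2.0,
            "forest": 1.5,
            "wetland": 1.0,
        }
    )

    def __post_init__(self) -> None:
        for name, kph in {**self.road_kph, **self.walk_kph}.items():
            if kph <= 0:
                raise ValueError(f"speed for class {name!r} must be > 0")


def build_cost_surface(
    surface_raster: Raster,
    road_raster: Raster | None,
    sched: SpeedSchedule = SpeedSchedule(),
) -> Raster:
    """Per-cell traversal speed (kph): road class overrides surface class.

    Clients are assumed to walk off-road and switch to motorized transport on
    reaching a roadway, so wherever a road crosses a cell the road speed
    wins. No-data in both rasters means impassable. Raises
    :class:`ScheduleCoverageError` for a class without a schedule entry.
    """
    if road_raster is not None and not surface_raster.aligned_with(road_raster):
        raise ValueError("surface and road rasters are not aligned")

    def class_speeds(raster: Raster, table: Mapping[str, float], kind: str) -> np.ndarray:
        legend = raster.legend or {}
        speeds = np.full(raster.shape, np.nan)
        codes = raster.data
        for code in np.unique(codes[~np.isnan(codes)]):
            name = legend.get(int(code), str(int(code)))
            if name not in table:
                raise ScheduleCoverageError(
                    f"no {kind} speed for class {name!r} (code {int(code)})"
                )
            speeds[codes == code] = table[name]
        return speeds

    speed = class_speeds(surface_raster, sched.walk_kph, "walking")
    if road_raster is not None:
        road_speed = class_speeds(road_raster, sched.road_kph, "road")
        speed = np.where(np.isnan(road_speed), speed, road_speed)
    return surface_raster.copy_with(speed)


def _snap_source(
    cs: Raster, point: tuple[float, float], max_snap_cells: int
) -> tuple[int, int]:
    row, col = cs.point_to_index(*point)  # raises if outside the raster
    passable = ~np.isnan(cs.data)
    if passable[row, col]:
        return row, col
    rows, cols = np.nonzero(passable)
    if len(rows) == 0:
        raise ValueError("cost surface is entirely impassable")
    d2 = (rows - row) ** 2 + (cols - col) ** 2
    best = int(np.argmin(d2))
    if d2[best] > max_snap_cells**2:
        raise ValueError(
            f"source {point} is more than {max_snap_cells} cells from any passable cell"
        )
    return int(rows[best]), int(cols[best])


def accumulate_travel_time(
    cs: Raster,
    sources: Sequence[tuple[float, float]],
    max_snap_cells: int = 5,
) -> Raster:
    """Minutes from every cell to its nearest source, over the cost surface.

    Multi-source Dijkstra on the 8-connected cell graph. A step between
    adjacent cells costs ``d * (t_a + t_b) / 2`` where ``d`` is the
    center-to-center distance (cell size, or cell size * sqrt(2) diagonally)
    and ``t_c`` is cell *c*'s traversal cost in minutes per meter. Source
    cells are zero; impassable or unreachable cells are NaN.

    Sources falling outside the raster raise; sources on impassable cells
    snap to the nearest passable cell within ``max_snap_cells`` cells.
    """
    if not sources:
        raise ValueError("at least one source is required")
    outside = [p for p in sources if not _inside(cs, p)]
    if outside:
        raise ValueError(f"source(s) outside raster extent: {outside}")
    source_cells = {_snap_source(cs, p, max_snap_cells) for p in sources}

    n_rows, n_cols = cs.shape
    # minutes per meter at each cell; NaN = impassable
    with np.errstate(divide="ignore", invalid="ignore"):
        min_per_m = 60.0 / (cs.data * 1000.0)
    dist = np.full(cs.shape, np.inf)
    heap: list[tuple[float, int, int]] = []
    for r, c in source_cells:
        dist[r, c] = 0.0
        heapq.heappush(heap, (0.0, r, c))

    steps = [
        (dr, dc, cs.cell_size * (SQRT2 if dr and dc else 1.0))
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
    ]
    while heap:
        d, r, c = heapq.heappop(heap)
        if d > dist[r, c]:
            continue
        t_here = min_per_m[r, c]
        for dr, dc, length in steps:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                continue
            t_there = min_per_m[nr, nc]
            if np.isnan(t_there):
                continue
            nd = d + length * (t_here + t_there) / 2.0
            if nd < dist[nr, nc]:
                dist[nr, nc] = nd
                heapq.heappush(heap, (nd, nr, nc))

    out = np.where(np.isinf(dist), np.nan, dist)
    out[np.isnan(cs.data)] = np.nan
    return cs.copy_with(out)


def _inside(raster: Raster, p: tuple[float, float]) -> bool:
    try:
        raster.point_to_index(*p)
    except ValueError:
        return False
    return True


# ---------------------------------------------------------------------------
# banding and population overlay
# ---------------------------------------------------------------------------

def band_index(minutes, band_width_min: float = 60.0, n_bands: int = 4):
    """Band number(s) for one-way minutes: floor(m / width), capped at the
    open-ended last band; NaN (unreachable) maps to -1."""
    m = np.asarray(minutes, dtype=float)
    if np.any(m[~np.isnan(m)] < 0):
        raise ValueError("travel minutes must be non-negative")
    idx = np.where(np.isnan(m), -1, np.minimum(m // band_width_min, n_bands - 1))
    return idx.astype(int) if idx.ndim else int(idx)


def band_minutes(minutes, band_width_min: float = 60.0):
    """Hourly band label(s) for minutes: half-open [60k, 60(k+1)), "3+" cap."""
    idx = band_index(minutes, band_width_min)
    if np.ndim(idx) == 0:
        return UNREACHABLE if idx < 0 else BAND_LABELS[idx]
    flat = np.asarray(idx)
    labels = np.where(flat < 0, UNREACHABLE, np.array(BAND_LABELS)[np.clip(flat, 0, 3)])
    return labels


@dataclass
class AccessTable:
    """Population counts and shares of women of reproductive age per band."""

    table: pd.DataFrame  # index = band labels + "Total"; columns: population, percent

    @classmethod
    def from_band_populations(cls, pop_by_band: Sequence[float]) -> "AccessTable":
        counts = np.asarray(pop_by_band, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("total population is zero")
        # largest-remainder rounding to one decimal so shares sum to 100.0
        raw = 1000.0 * counts / total
        floors = np.floor(raw).astype(int)
        short = 1000 - floors.sum()
        order = np.argsort(-(raw - floors), kind="stable")
        tenths = floors.copy()
        tenths[order[:short]] += 1
        percent = tenths / 10.0
        table = pd.DataFrame(
            {"population": counts, "percent": percent}, index=list(BAND_LABELS)
        )
        table.loc["Total"] = [total, percent.sum()]
        table.index.name = "Hours of travel time"
        return cls(table=table)

    @property
    def percents(self) -> pd.Series:
        return self.table.loc[list(BAND_LABELS), "percent"]

    @property
    def populations(self) -> pd.Series:
        return self.table.loc[list(BAND_LABELS), "population"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.1f")


def population_by_band(
    bands,
    pop: Raster,
    polygons: Sequence[Polygon] | None = None,
) -> AccessTable:
    """Overlay population on travel-time bands.

    Raster mode: ``bands`` is a travel-time or band-index raster aligned with
    ``pop``; every cell's population goes to its band. Polygon mode:
    ``bands`` is a per-polygon minutes sequence and ``polygons`` the matching
    neighborhood polygons; each population cell is assigned to the polygon
    containing its center and the polygon's population to its band.
    Unreachable (NaN) locations are excluded from every band and from the
    total.
    """
    counts = np.zeros(len(BAND_LABELS))
    if polygons is None:
        if not isinstance(bands, Raster):
            raise TypeError("raster mode requires a Raster of minutes")
        if not bands.aligned_with(pop):
            raise ValueError("band raster and population raster are not aligned")
        idx = band_index(bands.data)
        pop_data = np.where(np.isnan(pop.data), 0.0, pop.data)
        for k in range(len(BAND_LABELS)):
            counts[k] = pop_data[idx == k].sum()
    else:
        minutes = np.asarray(bands, dtype=float)
        if len(minutes) != len(polygons):
            raise ValueError("one minutes value per polygon is required")
        poly_idx = band_index(minutes)
        tree = STRtree(list(polygons))
        X, Y = pop.cell_centers()
        pts = MultiPoint(list(zip(X.ravel(), Y.ravel())))
        pairs = tree.query(list(pts.geoms), predicate="intersects")
        pop_flat = np.where(np.isnan(pop.data), 0.0, pop.data).ravel()
        assigned = {}
        for cell_i, poly_i in zip(*pairs):
            # boundary ties: keep the lowest polygon index, deterministically
            if cell_i not in assigned or poly_i < assigned[cell_i]:
                assigned[cell_i] = poly_i
        for cell_i, poly_i in assigned.items():
            k = poly_idx[poly_i]
            if k >= 0:
                counts[k] += pop_flat[cell_i]
    return AccessTable.from_band_populations(counts)


# ---------------------------------------------------------------------------
# end-to-end model
# ---------------------------------------------------------------------------

@dataclass
class RuralGeography:
    surface_raster: Raster
    road_raster: Raster | None
    population_raster: Raster
    schedule: SpeedSchedule = field(default_factory=SpeedSchedule)


@dataclass
class UrbanGeography:
    network: RoadNetwork
    neighborhood_points: Sequence[tuple[float, float]]
    boundary: Polygon
    population_raster: Raster | None = None
    neighborhood_population: Sequence[float] | None = None
    config: UrbanModelConfig = field(default_factory=UrbanModelConfig)


@dataclass
class AccessResult:
    table: AccessTable
    #: rural: accumulated minutes raster; urban: per-neighborhood frame
    travel_time: Raster | pd.DataFrame
    ready_facility_ids: list[str]


def ready_facilities(
    facilities: Sequence[FacilityRecord],
    readiness: Mapping[str, ReadinessResult],
    level: Level,
    assumed_levels: Mapping[str, Level] | None = None,
) -> list[FacilityRecord]:
    """Facilities ready at >= ``level``; unassessed ones count only if the
    caller assigned them an assumed level."""
    assumed = assumed_levels or {}
    out = []
    for f in facilities:
        if f.assessed:
            r = readiness.get(f.facility_id)
            if r is not None and r.level >= level:
                out.append(f)
        elif assumed.get(f.facility_id, None) is not None:
            if assumed[f.facility_id] >= level:
                out.append(f)
    return out


def run_access_model(
    facilities: Sequence[FacilityRecord],
    readiness: Mapping[str, ReadinessResult],
    level: Level,
    geography: RuralGeography | UrbanGeography,
    assumed_levels: Mapping[str, Level] | None = None,
) -> AccessResult:
    """Band one-way travel time to the nearest ready facility and overlay
    population. Raises :class:`NoReadyFacilityError` if no facility
    qualifies at ``level``."""
    ready = ready_facilities(facilities, readiness, level, assumed_levels)
    if not ready:
        raise NoReadyFacilityError(
            f"no facility ready at level {Level(level).name}"
        )
    sources = [f.location for f in ready]
    ids = [f.facility_id for f in ready]
    if isinstance(geography, RuralGeography):
        cs = build_cost_surface(
            geography.surface_raster, geography.road_raster, geography.schedule
        )
        tt = accumulate_travel_time(cs, sources)
        table = population_by_band(tt, geography.population_raster)
        return AccessResult(table=table, travel_time=tt, ready_facility_ids=ids)
    minutes = urban_travel_time(
        geography.neighborhood_points, sources, geography.network, geography.config
    )
    polys = thiessen_polygons(geography.neighborhood_points, geography.boundary)
    if geography.neighborhood_population is not None:
        pops = np.asarray(geography.neighborhood_population, dtype=float)
        counts = np.zeros(len(BAND_LABELS))
        for k, m in zip(band_index(minutes), pops):
            if k >= 0:
                counts[k] += m
        table = AccessTable.from_band_populations(counts)
    elif geography.population_raster is not None:
        table = population_by_band(
            minutes, geography.population_raster, polygons=polys
        )
    else:
        raise ValueError("urban geography needs a population raster or counts")
    frame = pd.DataFrame(
        {
            "x": [p[0] for p in geography.neighborhood_points],
            "y": [p[1] for p in geography.neighborhood_points],
            "minutes": minutes,
            "band": band_minutes(minutes),
        }
    )
    return AccessResult(table=table, travel_time=frame, ready_facility_ids=ids)
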