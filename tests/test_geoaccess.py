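import math

import networkx as nx
import numpy as np
import pytest
from shapely.geometry import Point, box

from implant_access import (
    Level,
    Raster,
    RoadNetwork,
    SpeedSchedule,
    UrbanModelConfig,
    accumulate_travel_time,
    band_minutes,
    build_cost_surface,
    population_by_band,
    run_access_model,
    snap_to_network,
    thiessen_polygons,
    urban_travel_time,
)
from implant_access.geoaccess import (
    NoReadyFacilityError,
    RuralGeography,
    ScheduleCoverageError,
    UrbanGeography,
    band_index,
)
from implant_access.synthetic import SyntheticGeoSpec, gen_urban_scenario

from conftest import materialized_dijkstra


def line_network(length_km=5.0):
    """Two nodes joined by a single road of the given length."""
    nodes = {"a": (0.0, 0.0), "b": (length_km * 1000.0, 0.0)}
    return RoadNetwork.from_edges(
        nodes, [("a", "b", length_km * 1000.0, "street")]
    )


class TestSnap:
    def test_coincident_point_snaps_to_node(self):
        net = line_network()
        assert snap_to_network((0.0, 0.0), net) == "a"

    def test_equidistant_tie_breaks_to_smallest_id(self):
        net = line_network(2.0)
        assert snap_to_network((1000.0, 500.0), net) == "a"

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        nodes = {
            f"n{i}": (float(x), float(y))
            for i, (x, y) in enumerate(rng.uniform(0, 1000, size=(30, 2)))
        }
        net = RoadNetwork(nx.Graph())
        for nid, (x, y) in nodes.items():
            net.graph.add_node(nid, x=x, y=y)
        for _ in range(50):
            p = tuple(rng.uniform(0, 1000, 2))
            best = min(
                nodes,
                key=lambda nid: (math.hypot(nodes[nid][0] - p[0], nodes[nid][1] - p[1]), nid),
            )
            assert snap_to_network(p, net) == best

    def test_empty_network_raises(self):
        with pytest.raises(ValueError):
            snap_to_network((0, 0), RoadNetwork(nx.Graph()))


class TestUrbanTravelTime:
    def test_five_km_at_defaults_is_80_minutes(self):
        net = line_network(5.0)
        minutes = urban_travel_time([(0.0, 0.0)], [(5000.0, 0.0)], net)
        assert minutes[0] == pytest.approx(80.0)

    def test_co_snapped_origin_pays_wait_only(self):
        net = line_network()
        minutes = urban_travel_time([(0.0, 0.0)], [(10.0, 0.0)], net)
        assert minutes[0] == pytest.approx(50.0)

    def test_wait_time_is_floor_everywhere(self):
        sc = gen_urban_scenario(SyntheticGeoSpec(n_neighborhoods=40, seed=3))
        minutes = urban_travel_time(
            sc.neighborhood_points, sc.facility_points, sc.network
        )
        assert np.all(minutes[~np.isnan(minutes)] >= 50.0)

    def test_matches_floyd_warshall_oracle_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            n = 8
            xy = rng.uniform(0, 2000, size=(n, 2))
            nodes = {f"n{i}": tuple(map(float, xy[i])) for i in range(n)}
            g = nx.Graph()
            edges = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        d = float(np.hypot(*(xy[i] - xy[j])))
                        if d > 0:
                            edges.append((f"n{i}", f"n{j}", d, "street"))
            if not edges:
                continue
            net = RoadNetwork.from_edges(nodes, edges, length_tolerance=1e-6)
            fw = nx.floyd_warshall(net.graph, weight="length_m")
            cfg = UrbanModelConfig()
            origins = [nodes[f"n{i}"] for i in range(n)]
            facilities = [nodes["n0"], nodes[f"n{n - 1}"]]
            got = urban_travel_time(origins, facilities, net, cfg)
            for i in range(n):
                d = min(fw[f"n{i}"].get("n0", np.inf), fw[f"n{i}"].get(f"n{n - 1}", np.inf))
                expect = np.nan if np.isinf(d) else 50.0 + 60.0 * d / 1000.0 / 10.0
                if np.isnan(expect):
                    assert np.isnan(got[i])
                else:
                    assert got[i] == pytest.approx(expect)

    def test_unreachable_origin_is_nan_with_warning(self):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "c": (9000.0, 9000.0)}
        net = RoadNetwork.from_edges(nodes, [("a", "b", 100.0, "s")])
        with pytest.warns(UserWarning, match="unreachable"):
            minutes = urban_travel_time([(9000.0, 9000.0)], [(0.0, 0.0)], net)
        assert np.isnan(minutes[0])

    def test_inconsistent_edge_length_rejected(self):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0)}
        with pytest.raises(ValueError, match="inconsistent"):
            RoadNetwork.from_edges(nodes, [("a", "b", 500.0, "s")])
        net = RoadNetwork.from_edges(nodes, [("a", "b", 500.0, "s")], length_tolerance=None)
        assert net.graph["a"]["b"]["length_m"] == 500.0


class TestThiessen:
    def test_single_point_gets_whole_boundary(self):
        b = box(0, 0, 10, 10)
        polys = thiessen_polygons([(3.0, 3.0)], b)
        assert len(polys) == 1
        assert polys[0].equals(b)

    def test_two_points_split_by_perpendicular_bisector(self):
        b = box(0, 0, 10, 10)
        left, right = thiessen_polygons([(2.0, 5.0), (8.0, 5.0)], b)
        assert left.equals(box(0, 0, 5, 10))
        assert right.equals(box(5, 0, 10, 10))

    def test_partition_and_nearest_seed(self):
        rng = np.random.default_rng(9)
        b = box(0, 0, 100, 100)
        seeds = [tuple(p) for p in rng.uniform(5, 95, size=(12, 2))]
        polys = thiessen_polygons(seeds, b)
        assert sum(p.area for p in polys) == pytest.approx(b.area)
        pts = rng.uniform(0, 100, size=(300, 2))
        for x, y in pts:
            d = [math.hypot(x - sx, y - sy) for sx, sy in seeds]
            nearest = int(np.argmin(d))
            containing = [i for i, p in enumerate(polys) if p.covers(Point(x, y))]
            assert nearest in containing

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            thiessen_polygons([(1.0, 1.0), (1.0, 1.0)], box(0, 0, 5, 5))


class TestCostSurface:
    def test_road_overrides_surface(self):
        surface = Raster(np.zeros((2, 2)), 100.0, legend={0: "grassland"})
        road = Raster(
            np.array([[0.0, np.nan], [np.nan, np.nan]]), 100.0, legend={0: "primary"}
        )
        cs = build_cost_surface(surface, road)
        assert cs.data[0, 0] == 60.0
        assert cs.data[0, 1] == 2.5

    def test_wetland_walking_speed(self):
        surface = Raster(np.full((1, 1), 3.0), 100.0, legend={3: "wetland"})
        assert build_cost_surface(surface, None).data[0, 0] == 1.0

    def test_all_nodata_is_all_impassable(self):
        surface = Raster(np.full((3, 3), np.nan), 100.0)
        cs = build_cost_surface(surface, None)
        assert np.isnan(cs.data).all()

    def test_unknown_class_names_the_class(self):
        surface = Raster(np.zeros((1, 1)), 100.0, legend={0: "lava"})
        with pytest.raises(ScheduleCoverageError, match="lava"):
            build_cost_surface(surface, None)

    def test_misaligned_rasters_rejected(self):
        surface = Raster(np.zeros((2, 2)), 100.0, legend={0: "grassland"})
        road = Raster(np.zeros((3, 3)), 100.0, legend={0: "primary"})
        with pytest.raises(ValueError, match="aligned"):
            build_cost_surface(surface, road)


class TestAccumulate:
    def test_axial_steps_on_uniform_surface(self, uniform_surface):
        src = [uniform_surface.index_to_point(10, 10)]
        tt = accumulate_travel_time(uniform_surface, src)
        assert tt.data[10, 10] == 0.0
        assert tt.data[10, 20] == pytest.approx(24.0)  # 1000 m at 2.5 kph

    def test_single_diagonal_step(self, uniform_surface):
        src = [uniform_surface.index_to_point(10, 10)]
        tt = accumulate_travel_time(uniform_surface, src)
        expect = 100.0 * math.sqrt(2) * 60.0 / 2500.0
        assert tt.data[11, 11] == pytest.approx(expect)

    def test_octile_bound_on_uniform_surface(self, uniform_surface):
        src_pt = uniform_surface.index_to_point(10, 10)
        tt = accumulate_travel_time(uniform_surface, [src_pt])
        X, Y = uniform_surface.cell_centers()
        d = np.hypot(X - src_pt[0], Y - src_pt[1])
        v = 2.5 * 1000.0 / 60.0  # meters per minute
        assert np.all(tt.data >= d / v - 1e-9)
        assert np.all(tt.data <= 1.0824 * d / v + 1e-9)

    def test_matches_materialized_graph_oracle(self):
        rng = np.random.default_rng(21)
        for trial in range(5):
            data = rng.uniform(1.0, 60.0, size=(15, 15))
            data[rng.random((15, 15)) < 0.15] = np.nan
            data[0, 0] = 10.0
            cs = Raster(data, 100.0)
            tt = accumulate_travel_time(cs, [cs.index_to_point(0, 0)])
            oracle = materialized_dijkstra(data, 100.0, [(0, 0)])
            np.testing.assert_allclose(tt.data, oracle, equal_nan=True)

    def test_adding_source_never_increases_time(self, uniform_surface):
        one = accumulate_travel_time(uniform_surface, [uniform_surface.index_to_point(0, 0)])
        two = accumulate_travel_time(
            uniform_surface,
            [uniform_surface.index_to_point(0, 0), uniform_surface.index_to_point(20, 20)],
        )
        assert np.all(two.data <= one.data + 1e-12)

    def test_impassable_source_snaps_within_limit(self):
        data = np.full((9, 9), 2.5)
        data[4, 4] = np.nan
        cs = Raster(data, 100.0)
        tt = accumulate_travel_time(cs, [cs.index_to_point(4, 4)])
        assert np.nanmin(tt.data) == 0.0

    def test_source_outside_raster_raises(self, uniform_surface):
        with pytest.raises(ValueError, match="outside"):
            accumulate_travel_time(uniform_surface, [(-5000.0, -5000.0)])

    def test_no_passable_cell_near_source_raises(self):
        data = np.full((20, 20), np.nan)
        data[0, 0] = 2.5
        cs = Raster(data, 100.0)
        with pytest.raises(ValueError, match="passable"):
            accumulate_travel_time(cs, [cs.index_to_point(19, 19)])


class TestBanding:
    @pytest.mark.parametrize(
        "minutes, label",
        [(0.0, "0-1"), (59.99, "0-1"), (60.0, "1-2"), (119.9, "1-2"), (200.0, "3+")],
    )
    def test_half_open_hourly_bands(self, minutes, label):
        assert band_minutes(minutes) == label

    def test_nodata_is_unreachable(self):
        assert band_minutes(float("nan")) == "unreachable"

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError):
            band_minutes(-1.0)

    def test_array_banding(self):
        idx = band_index(np.array([0.0, 61.0, np.nan, 500.0]))
        assert list(idx) == [0, 1, -1, 3]


class TestPopulationOverlay:
    def test_proportions_conserved_and_sum_100(self, uniform_surface):
        tt = accumulate_travel_time(uniform_surface, [uniform_surface.index_to_point(10, 10)])
        pop = uniform_surface.copy_with(np.full((21, 21), 10.0))
        table = population_by_band(tt, pop)
        assert table.populations.sum() == pytest.approx(21 * 21 * 10.0)
        assert table.percents.sum() == pytest.approx(100.0, abs=0.1)

    def test_all_cells_within_first_band(self):
        tt = Raster(np.full((4, 4), 30.0), 100.0)
        pop = Raster(np.ones((4, 4)), 100.0)
        table = population_by_band(tt, pop)
        assert table.percents["0-1"] == 100.0
        assert table.percents["1-2"] == 0.0

    def test_manual_cell_tally(self):
        minutes = np.array([[10.0, 70.0], [130.0, 200.0]])
        pop = np.array([[1.0, 2.0], [3.0, 4.0]])
        table = population_by_band(Raster(minutes, 100.0), Raster(pop, 100.0))
        assert list(table.populations) == [1.0, 2.0, 3.0, 4.0]
        assert table.percents["0-1"] == 10.0

    def test_zero_population_rejected(self):
        tt = Raster(np.zeros((2, 2)), 100.0)
        with pytest.raises(ValueError, match="zero"):
            population_by_band(tt, Raster(np.zeros((2, 2)), 100.0))

    def test_misaligned_grids_rejected(self):
        tt = Raster(np.zeros((2, 2)), 100.0)
        with pytest.raises(ValueError, match="aligned"):
            population_by_band(tt, Raster(np.zeros((3, 3)), 100.0))

    def test_polygon_mode_matches_direct_tally(self):
        b = box(0, 0, 200, 200)
        polys = thiessen_polygons([(50.0, 100.0), (150.0, 100.0)], b)
        pop = Raster(np.ones((2, 2)), 100.0)  # one cell center per quadrant
        table = population_by_band([30.0, 90.0], pop, polygons=polys)
        assert table.populations["0-1"] == 2.0
        assert table.populations["1-2"] == 2.0


class TestRunAccessModel:
    def test_more_ready_facilities_never_slower(self, fixture_records, fixture_readiness):
        surface = Raster(
            np.zeros((40, 40)),
            1000.0,
            origin=(28000.0, -2000.0),
            legend={0: "grassland"},
        )
        pop = Raster(np.ones((40, 40)), 1000.0, origin=(28000.0, -2000.0))
        kolda = [f for f in fixture_records if f.district.value == "KOLDA"]
        geo = RuralGeography(surface, None, pop)
        all_ready = run_access_model(
            kolda, fixture_readiness, Level.REGULAR, geo
        )
        difficult_only = run_access_model(
            kolda, fixture_readiness, Level.DIFFICULT, geo
        )
        assert len(all_ready.ready_facility_ids) > len(difficult_only.ready_facility_ids)
        assert np.all(
            all_ready.travel_time.data <= difficult_only.travel_time.data + 1e-9
        )
        # cumulative within-k-hours population share never lower with more facilities
        assert (
            all_ready.table.percents.cumsum() >= difficult_only.table.percents.cumsum() - 0.11
        ).all()

    def test_no_ready_facility_is_error_not_empty_table(self, fixture_records, fixture_readiness):
        dakar = [f for f in fixture_records if f.district.value == "DAKAR_CENTRE"]
        not_ready = [f for f in dakar if fixture_readiness[f.facility_id].level == Level.NOT_READY]
        surface = Raster(np.zeros((5, 5)), 1000.0, legend={0: "grassland"})
        geo = RuralGeography(surface, None, Raster(np.ones((5, 5)), 1000.0))
        with pytest.raises(NoReadyFacilityError):
            run_access_model(not_ready, fixture_readiness, Level.REGULAR, geo)

    def test_assumed_level_admits_unassessed_hospital(self, fixture_records, fixture_readiness):
        hospital = [f for f in fixture_records if not f.assessed]
        surface = Raster(
            np.zeros((10, 10)), 1000.0, origin=(28000.0, 4000.0), legend={0: "grassland"}
        )
        geo = RuralGeography(surface, None, Raster(np.ones((10, 10)), 1000.0, origin=(28000.0, 4000.0)))
        with pytest.raises(NoReadyFacilityError):
            run_access_model(hospital, fixture_readiness, Level.DIFFICULT, geo)
        result = run_access_model(
            hospital,
            fixture_readiness,
            Level.DIFFICULT,
            geo,
            assumed_levels={"K00": Level.DIFFICULT},
        )
        assert result.ready_facility_ids == ["K00"]

    def test_urban_dispatch(self, fixture_records, fixture_readiness):
        sc = gen_urban_scenario(SyntheticGeoSpec(n_neighborhoods=30, seed=8))
        dakar = [f for f in fixture_records if f.district.value == "DAKAR_CENTRE"]
        geo = UrbanGeography(
            network=sc.network,
            neighborhood_points=sc.neighborhood_points,
            boundary=sc.boundary,
            neighborhood_population=sc.neighborhood_population,
        )
        result = run_access_model(dakar, fixture_readiness, Level.REGULAR, geo)
        assert result.table.percents.sum() == pytest.approx(100.0, abs=0.1)
        assert (result.travel_time["minutes"] >= 50.0).all()
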