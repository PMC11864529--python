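"""Routing substrate: snapping, mode-aware shortest times, matrices, I/O."""

import math

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from aedsim.network import (
    Edge,
    PointSet,
    RoadNetwork,
    SitePoint,
    TravelTimeMatrix,
    get_mode,
    read_network_geojson,
    read_points_geojson,
    shortest_travel_time,
    snap_points,
    travel_time_matrix,
    write_network_geojson,
    write_points_geojson,
)
from conftest import all_node_pointset, make_random_network


def dense_time_matrix(net: RoadNetwork, mode) -> np.ndarray:
    """Independent all-pairs oracle: adjacency in seconds + Floyd–Warshall."""
    ids = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(ids)}
    m = np.full((len(ids), len(ids)), np.inf)
    for e in net.edges:
        speed = mode.speed_kmh
        if e.speed_override and mode.name in e.speed_override:
            speed = e.speed_override[mode.name]
        t = e.length_m * 3.6 / speed
        i, j = idx[e.u], idx[e.v]
        m[i, j] = min(m[i, j], t)
        if not (e.oneway and mode.name in ("car", "bicycle", "ambulance")):
            m[j, i] = min(m[j, i], t)
    return floyd_warshall(m)


class TestModesAndEdges:
    def test_default_speeds(self):
        assert get_mode("walk").speed_kmh == 10.0
        assert get_mode("ambulance").speed_kmh == 50.0
        assert not get_mode("walk").directed
        assert get_mode("car").directed

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown mode"):
            get_mode("teleport")

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError, match="length"):
            RoadNetwork({"a": (0, 0), "b": (1, 0)}, [Edge("a", "b", 0.0)])
        with pytest.raises(ValueError, match="endpoint"):
            RoadNetwork({"a": (0, 0)}, [Edge("a", "zz", 10.0)])


class TestSnapping:
    def test_exact_coincidence(self):
        net = RoadNetwork({"n1": (0.0, 0.0), "n2": (100.0, 0.0)}, [Edge("n1", "n2", 100.0)])
        ps = PointSet([SitePoint("d1", 0.0, 0.0, "demand")])
        assert snap_points(net, ps).points[0].snapped_node == "n1"

    def test_equidistant_tie_breaks_to_lowest_id(self):
        net = RoadNetwork({"n1": (0.0, 0.0), "n2": (100.0, 0.0)}, [Edge("n1", "n2", 100.0)])
        ps = PointSet([SitePoint("d1", 50.0, 0.0, "demand")])
        assert snap_points(net, ps).points[0].snapped_node == "n1"

    def test_empty_network_errors(self):
        with pytest.raises(ValueError, match="no nodes"):
            snap_points(RoadNetwork({}, []), PointSet([SitePoint("d1", 0, 0, "demand")]))

    def test_matches_brute_force_nearest_neighbour(self, rng):
        net = make_random_network(rng, n_nodes=25)
        pts = PointSet(
            [
                SitePoint(f"d{i:02d}", float(x), float(y), "demand")
                for i, (x, y) in enumerate(rng.uniform(-100, 1100, size=(20, 2)))
            ]
        )
        snapped = snap_points(net, pts)
        for p in snapped:
            dists = {
                nid: math.dist((p.x, p.y), xy) for nid, xy in net.nodes.items()
            }
            best = min(dists.values())
            expected = min(n for n, d in dists.items() if d == best)
            assert p.snapped_node == expected

    def test_original_coordinates_preserved(self, rng):
        net = make_random_network(rng, n_nodes=10)
        pts = PointSet([SitePoint("d1", 123.4, 567.8, "demand")])
        out = snap_points(net, pts).points[0]
        assert (out.x, out.y) == (123.4, 567.8)


class TestShortestTravelTime:
    def test_single_edge_walk_and_ambulance(self):
        net = RoadNetwork({"a": (0, 0), "b": (500, 0)}, [Edge("a", "b", 500.0)])
        assert shortest_travel_time(net, "a", "b", get_mode("walk")) == pytest.approx(180.0)
        assert shortest_travel_time(net, "a", "b", get_mode("ambulance")) == pytest.approx(36.0)

    def test_oneway_blocks_car_but_not_walk(self):
        net = RoadNetwork(
            {"u": (0, 0), "v": (500, 0)}, [Edge("v", "u", 500.0, oneway=True)]
        )
        assert shortest_travel_time(net, "u", "v", get_mode("car")) == math.inf
        assert shortest_travel_time(net, "u", "v", get_mode("walk")) == pytest.approx(180.0)

    def test_origin_equals_dest_is_zero(self, line_network):
        assert shortest_travel_time(line_network, "b", "b", get_mode("car")) == 0.0

    def test_unknown_node_errors(self, line_network):
        with pytest.raises(KeyError):
            shortest_travel_time(line_network, "a", "zzz", get_mode("walk"))

    def test_matches_floyd_warshall_oracle(self, rng):
        for _ in range(5):
            net = make_random_network(rng, n_nodes=20, n_extra_edges=25)
            for mode_name in ("walk", "car"):
                mode = get_mode(mode_name)
                oracle = dense_time_matrix(net, mode)
                ids = sorted(net.nodes)
                for i in range(0, 20, 7):
                    for j in range(0, 20, 5):
                        got = shortest_travel_time(net, ids[i], ids[j], mode)
                        assert got == pytest.approx(oracle[i, j], rel=1e-12, abs=1e-9)


class TestTravelTimeMatrix:
    def test_single_point_is_zero_matrix(self, line_network):
        ps = PointSet([SitePoint("d1", 0.0, 0.0, "demand")])
        m = travel_time_matrix(line_network, ps, ps, get_mode("walk"))
        assert m.t.shape == (1, 1) and m.t[0, 0] == 0.0

    def test_matches_per_pair_calls(self, rng):
        net = make_random_network(rng, n_nodes=15)
        pts = all_node_pointset(net)
        origins = PointSet(pts.points[:5])
        dests = PointSet(pts.points[5:13])
        mode = get_mode("bicycle")
        m = travel_time_matrix(net, origins, dests, mode)
        for i, o in enumerate(origins):
            for j, d in enumerate(dests):
                expect = shortest_travel_time(net, o.snapped_node, d.snapped_node, mode)
                assert m.t[i, j] == pytest.approx(expect, rel=1e-12, abs=1e-12)

    def test_disconnected_destination_is_inf_column(self):
        nodes = {"a": (0.0, 0.0), "b": (100.0, 0.0), "z": (900.0, 900.0), "z2": (950.0, 900.0)}
        net = RoadNetwork(nodes, [Edge("a", "b", 100.0), Edge("z", "z2", 50.0)])
        origins = PointSet([SitePoint("o1", 0, 0, "demand", "a"), SitePoint("o2", 100, 0, "demand", "b")])
        dests = PointSet([SitePoint("d1", 900, 900, "candidate", "z")])
        m = travel_time_matrix(net, origins, dests, get_mode("walk"))
        assert np.all(np.isinf(m.t[:, 0]))

    def test_walk_matrix_is_symmetric(self, rng):
        net = make_random_network(rng, n_nodes=20)
        pts = all_node_pointset(net)
        m = travel_time_matrix(net, pts, pts, get_mode("walk")).t
        assert np.allclose(m, m.T, rtol=1e-12, atol=1e-9)

    def test_doubling_speed_halves_times(self, rng):
        net = make_random_network(rng, n_nodes=15, override_prob=0.0)
        pts = all_node_pointset(net)
        m1 = travel_time_matrix(net, pts, pts, get_mode("car", 20.0)).t
        m2 = travel_time_matrix(net, pts, pts, get_mode("car", 40.0)).t
        finite = np.isfinite(m1)
        assert np.allclose(m1[finite], 2.0 * m2[finite], rtol=1e-9)
        assert np.array_equal(np.isfinite(m1), np.isfinite(m2))

    def test_adding_edge_never_increases_times(self, rng):
        net = make_random_network(rng, n_nodes=15, n_extra_edges=10)
        pts = all_node_pointset(net)
        mode = get_mode("walk")
        before = travel_time_matrix(net, pts, pts, mode).t
        ids = sorted(net.nodes)
        augmented = RoadNetwork(
            dict(net.nodes), net.edges + [Edge(ids[0], ids[-1], 60.0)]
        )
        after = travel_time_matrix(augmented, pts, pts, mode).t
        assert np.all(after <= before + 1e-9)


class TestIO:
    def test_network_geojson_roundtrip(self, rng, tmp_path):
        net = make_random_network(rng, n_nodes=12, n_extra_edges=8)
        path = tmp_path / "net.geojson"
        write_network_geojson(net, path)
        back = read_network_geojson(path)
        assert back.n_nodes == net.n_nodes
        # routing is preserved even though node ids are regenerated
        mode = get_mode("walk")
        orig = np.sort(travel_time_matrix(net, all_node_pointset(net), all_node_pointset(net), mode).t, axis=None)
        rt = np.sort(travel_time_matrix(back, all_node_pointset(back), all_node_pointset(back), mode).t, axis=None)
        assert np.allclose(orig, rt, rtol=1e-9)

    def test_length_recomputed_from_geometry(self, tmp_path):
        import json

        fc = {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "geometry": {"type": "LineString", "coordinates": [[0, 0], [300, 400]]},
                    "properties": {},
                }
            ],
        }
        path = tmp_path / "net.geojson"
        path.write_text(json.dumps(fc))
        net = read_network_geojson(path)
        assert net.edges[0].length_m == pytest.approx(500.0)

    def test_points_geojson_roundtrip(self, tmp_path):
        ps = PointSet([SitePoint("d1", 1.5, 2.5, "demand", "n1"), SitePoint("d2", 3.0, 4.0, "demand")])
        path = tmp_path / "pts.geojson"
        write_points_geojson(ps, path)
        back = read_points_geojson(path)
        assert back.ids == ["d1", "d2"]
        assert back.points[0].snapped_node == "n1"
        assert back.points[1].snapped_node is None

    def test_matrix_csv_roundtrip_with_inf(self, tmp_path):
        o = PointSet([SitePoint("o1", 0, 0, "demand", "a")])
        d = PointSet(
            [SitePoint("d1", 0, 0, "candidate", "a"), SitePoint("d2", 1, 1, "candidate", "b")]
        )
        m = TravelTimeMatrix(o, d, get_mode("walk"), np.array([[12.5, math.inf]]))
        path = tmp_path / "m.csv"
        m.to_csv(path, provenance="seed=1")
        df = TravelTimeMatrix.read_csv(path)
        assert df.loc["o1", "d1"] == 12.5
        assert math.isinf(df.loc["o1", "d2"])

    def test_mixed_kinds_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            PointSet([SitePoint("a", 0, 0, "demand"), SitePoint("b", 0, 0, "station")])
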