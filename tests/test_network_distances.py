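"""Snap-node insertion, Dijkstra queries, buffer-capture curves."""

import numpy as np
import pytest

from conftest import make_graph, random_connected_graph
from foodscape.network_distances import (
    buffer_curve,
    dijkstra,
    euclidean_nearest,
    insert_snap_nodes,
    nearest_other_outlet_distances,
    nearest_school_distances,
)
from foodscape.poi_assignment import SnapResult


def snap(pid, eid, t):
    return SnapResult(poi_id=pid, edge_id=eid, snap_distance=0.0, offset_t=t)


class TestInsertSnapNodes:
    def test_midpoint_split_into_equal_children(self):
        g = make_graph([(0, 0), (10, 0)], [(0, 1, 10.0)])
        net = insert_snap_nodes(g, [snap("a", 0, 0.5)])
        lengths = sorted(e.length for e in net.graph.edges.values())
        assert lengths == pytest.approx([5.0, 5.0])
        assert net.graph.n == 3

    def test_colocated_pois_share_one_node(self):
        g = make_graph([(0, 0), (10, 0)], [(0, 1, 10.0)])
        net = insert_snap_nodes(g, [snap("a", 0, 0.3), snap("b", 0, 0.3)])
        assert net.poi_nodes["a"] == net.poi_nodes["b"]
        assert net.graph.n == 3

    def test_endpoint_snaps_reuse_endpoint_nodes(self):
        g = make_graph([(0, 0), (10, 0)], [(0, 1, 10.0)])
        net = insert_snap_nodes(g, [snap("a", 0, 0.0), snap("b", 0, 1.0)])
        assert net.graph.n == 2
        assert net.poi_nodes["a"] == 0 and net.poi_nodes["b"] == 1

    def test_random_snaps_conserve_total_length(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            g = random_connected_graph(rng)
            total = sum(e.length for e in g.edges.values())
            snaps = [
                snap(f"p{i}", int(rng.integers(0, g.m)), float(rng.uniform()))
                for i in range(int(rng.integers(1, 10)))
            ]
            net = insert_snap_nodes(g, snaps)
            new_total = sum(e.length for e in net.graph.edges.values())
            assert new_total == pytest.approx(total, rel=1e-9)


class TestDijkstra:
    def test_path_graph_distance_adds_up(self):
        g = make_graph([(0, 0), (1, 0), (3, 0)], [(0, 1, 1.0), (1, 2, 2.0)])
        net = insert_snap_nodes(g, [])
        dist = dijkstra(net, 0)
        assert dist[2] == pytest.approx(3.0)
        assert dist[0] == 0.0

    def test_unreachable_is_infinite(self):
        g = make_graph([(0, 0), (1, 0), (5, 5), (6, 5)],
                       [(0, 1, 1.0), (2, 3, 1.0)])
        dist = dijkstra(insert_snap_nodes(g, []), 0)
        assert np.isinf(dist[2]) and np.isinf(dist[3])

    def test_matches_simple_path_enumeration(self):
        """Exact agreement with exhaustive path enumeration on small graphs."""
        from _oracles import enumerate_shortest_paths

        rng = np.random.default_rng(6)
        for _ in range(25):
            g = random_connected_graph(rng, n_max=10)
            adj = {v: [] for v in g.nodes}
            for e in g.edges.values():
                adj[e.u].append((e.v, e.length))
                adj[e.v].append((e.u, e.length))
            dist = dijkstra(g, 0)
            expected = enumerate_shortest_paths(adj, 0)
            for v in g.nodes:
                assert dist[v] == pytest.approx(expected[v], rel=1e-12)

    def test_matches_networkx(self):
        import networkx as nx

        rng = np.random.default_rng(7)
        for _ in range(10):
            g = random_connected_graph(rng, n_max=30)
            dist = dijkstra(g, 0)
            nxg = g.to_networkx()
            expected = nx.single_source_dijkstra_path_length(nxg, 0)
            for v, d in expected.items():
                assert dist[v] == pytest.approx(d, rel=1e-9)


class TestNearestQueries:
    def test_school_colocated_with_outlet_is_zero(self):
        g = make_graph([(0, 0), (10, 0)], [(0, 1, 10.0)])
        net = insert_snap_nodes(g, [snap("o", 0, 0.4), snap("s", 0, 0.4)])
        out = nearest_school_distances(net, {"s": net.poi_nodes["s"]},
                                       {"o": net.poi_nodes["o"]})
        assert out["o"] == 0.0

    def test_multi_source_equals_per_school_minimum(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            g = random_connected_graph(rng, n_max=25)
            net = insert_snap_nodes(g, [])
            nodes = sorted(net.graph.nodes)
            schools = {f"s{i}": int(v) for i, v in
                       enumerate(rng.choice(nodes, size=3, replace=False))}
            outlets = {f"o{i}": int(v) for i, v in
                       enumerate(rng.choice(nodes, size=4, replace=False))}
            multi = nearest_school_distances(net, schools, outlets)
            per_school = {
                pid: min(dijkstra(net, sv)[ov] for sv in schools.values())
                for pid, ov in outlets.items()
            }
            for pid in outlets:
                assert multi[pid] == pytest.approx(per_school[pid], rel=1e-12)

    def test_outlet_in_disconnected_component_infinite(self):
        g = make_graph([(0, 0), (1, 0), (5, 5), (6, 5)],
                       [(0, 1, 1.0), (2, 3, 1.0)])
        net = insert_snap_nodes(g, [snap("o", 0, 0.5), snap("s", 1, 0.5)])
        out = nearest_school_distances(net, {"s": net.poi_nodes["s"]},
                                       {"o": net.poi_nodes["o"]})
        assert np.isinf(out["o"])

    def test_three_outlets_on_a_line(self):
        g = make_graph([(0, 0), (25, 0)], [(0, 1, 25.0)])
        net = insert_snap_nodes(
            g, [snap("a", 0, 0.0), snap("b", 0, 10 / 25), snap("c", 0, 1.0)]
        )
        nodes = {p: net.poi_nodes[p] for p in ("a", "b", "c")}
        out = nearest_other_outlet_distances(net, nodes)
        assert out["a"] == pytest.approx(10.0)
        assert out["b"] == pytest.approx(10.0)
        assert out["c"] == pytest.approx(15.0)

    def test_two_outlets_single_edge(self):
        g = make_graph([(0, 0), (30, 0)], [(0, 1, 30.0)])
        net = insert_snap_nodes(g, [snap("a", 0, 0.0), snap("b", 0, 1.0)])
        out = nearest_other_outlet_distances(
            net, {p: net.poi_nodes[p] for p in ("a", "b")}
        )
        assert out == {"a": pytest.approx(30.0), "b": pytest.approx(30.0)}

    def test_single_outlet_rejected(self):
        g = make_graph([(0, 0), (1, 0)], [(0, 1, 1.0)])
        net = insert_snap_nodes(g, [snap("a", 0, 0.5)])
        with pytest.raises(ValueError, match="two outlets"):
            nearest_other_outlet_distances(net, {"a": net.poi_nodes["a"]})

    def test_nearest_outlet_matches_all_pairs_oracle(self):
        """Early-termination Dijkstra equals the full all-pairs minimum."""
        rng = np.random.default_rng(9)
        g = random_connected_graph(rng, n_max=40)
        net = insert_snap_nodes(g, [])
        nodes = sorted(net.graph.nodes)
        picks = rng.choice(nodes, size=min(12, len(nodes)), replace=False)
        outlets = {f"o{i}": int(v) for i, v in enumerate(picks)}
        fast = nearest_other_outlet_distances(net, outlets)
        for pid, v in outlets.items():
            dist = dijkstra(net, v)
            expected = min(
                (dist[u] if u != v else (0.0 if sum(
                    1 for w in outlets.values() if w == v) > 1 else np.inf))
                for qid, u in outlets.items() if qid != pid
            )
            assert fast[pid] == pytest.approx(expected, rel=1e-12)


class TestEuclideanNearest:
    def test_example_and_identity(self):
        d = euclidean_nearest(np.array([[0.0, 0.0]]),
                              np.array([[3.0, 4.0], [10.0, 0.0]]))
        assert d[0] == pytest.approx(5.0)
        d = euclidean_nearest(np.array([[3.0, 4.0]]),
                              np.array([[3.0, 4.0], [10.0, 0.0]]))
        assert d[0] == 0.0

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(10)
        pts = rng.uniform(0, 100, size=(200, 2))
        targets = rng.uniform(0, 100, size=(50, 2))
        fast = euclidean_nearest(pts, targets)
        brute = np.min(
            np.hypot(pts[:, None, 0] - targets[None, :, 0],
                     pts[:, None, 1] - targets[None, :, 1]),
            axis=1,
        )
        assert np.allclose(fast, brute, rtol=1e-12)

    def test_exclude_self_with_colocated_pair(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 0.0]])
        d = euclidean_nearest(pts, pts, exclude_self=True)
        assert d[0] == 0.0 and d[1] == 0.0
        assert d[2] == pytest.approx(9.0)


class TestBufferCurve:
    def test_spec_bins_example(self):
        curve = buffer_curve([0, 10, 70, 700], np.arange(0, 601, 60.0))
        assert curve.zero_count == 1
        assert curve.bin_counts[0] == 1   # (0, 60]
        assert curve.bin_counts[1] == 1   # (60, 120]
        assert curve.overflow_count == 1

    def test_all_zeros_cumulative_one_at_first_edge(self):
        curve = buffer_curve([0.0, 0.0, 0.0], [0.0, 60.0])
        assert curve.fraction_within[0] == 1.0

    def test_cumulative_monotone_and_bounded(self):
        rng = np.random.default_rng(11)
        curve = buffer_curve(rng.uniform(0, 900, size=500))
        fw = curve.fraction_within
        assert all(b >= a for a, b in zip(fw, fw[1:]))
        assert fw[-1] <= 1.0
        assert curve.n_finite == 500

    def test_infinite_excluded_and_reported(self):
        curve = buffer_curve([10.0, np.inf, 20.0])
        assert curve.n_infinite == 1
        assert curve.n_finite == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            buffer_curve([])


class TestNetworkVsEuclidean:
    def test_network_never_below_euclidean(self, small_world):
        """Along-street distance can never beat the straight line."""
        from foodscape.pipeline import outlet_clustering_capture

        res = outlet_clustering_capture(small_world, 120.0)
        loc = {p.id: p.location for p in small_world.pois}
        xy = np.array([loc[pid] for pid in res["poi_ids"]], dtype=float)
        # Euclidean nearest over the full measured set is a lower bound for
        # the per-district network nearest-other-outlet distance
        euc = euclidean_nearest(xy, xy, exclude_self=True)
        finite = np.isfinite(res["distances"])
        assert finite.any()
        assert np.all(res["distances"][finite] >= euc[finite] - 1e-9)
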