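"""Shared fixtures: tiny hand-built graphs and a small synthetic world."""

import numpy as np
import pytest

from foodscape.geo_core import Point, Polyline
from foodscape.network_builder import Edge, StreetGraph


def make_graph(node_xy, edge_list, district_id="T") -> StreetGraph:
    """StreetGraph from node coordinates and (u, v, weight) triples.

    Edge geometry is the straight segment between the node coordinates,
    unless the stated weight differs from the Euclidean gap, in which case a
    bent two-leg polyline of the right length is synthesised (weights are
    lengths, and the invariant is enforced at build time).
    """
    g = StreetGraph(district_id=district_id)
    for i, (x, y) in enumerate(node_xy):
        g.nodes[i] = Point(float(x), float(y))
    for eid, (u, v, w) in enumerate(edge_list):
        a, b = g.nodes[u], g.nodes[v]
        direct = float(np.hypot(b.x - a.x, b.y - a.y))
        if abs(direct - w) < 1e-12 and direct > 0:
            geom = Polyline([a, b])
        else:
            # detour through an off-axis apex so the polyline length equals w
            if direct >= w or direct == 0.0:
                mid = Point((a.x + b.x) / 2 + w, (a.y + b.y) / 2 + 1.0)
                geom = Polyline([a, mid, b])
            else:
                h = 0.5 * np.sqrt(w**2 - direct**2)
                nx_, ny_ = -(b.y - a.y) / direct, (b.x - a.x) / direct
                mid = Point((a.x + b.x) / 2 + nx_ * h, (a.y + b.y) / 2 + ny_ * h)
                geom = Polyline([a, mid, b])
        g.edges[eid] = Edge(u=u, v=v, length=float(w), geometry=geom,
                            segment_id=f"s{eid}")
    return g


def random_connected_graph(rng, n_max=12, integer_weights=False) -> StreetGraph:
    """Random connected weighted graph: a spanning tree plus extra edges."""
    n = int(rng.integers(3, n_max + 1))
    xy = rng.uniform(0, 100, size=(n, 2))
    edges = []
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.append((u, v))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = rng.integers(0, n, size=2)
        if u != v and (min(u, v), max(u, v)) not in {(min(a, b), max(a, b)) for a, b in edges}:
            edges.append((int(u), int(v)))
    if integer_weights:
        weights = rng.integers(1, 6, size=len(edges)).astype(float)
    else:
        weights = rng.uniform(0.5, 10.0, size=len(edges))
    return make_graph(xy, [(u, v, float(w)) for (u, v), w in zip(edges, weights)])


@pytest.fixture(scope="session")
def small_world():
    """Two 3 km districts, ~120 nodes each; shared across read-only tests."""
    from foodscape.synthetic_geodata import SyntheticConfig, generate_world

    cfg = SyntheticConfig(
        seed=11, n_districts=2, district_size_m=3000.0, road_grid_pitch_m=300.0,
        n_outlets=80, n_schools=12, outlet_pair_radius_m=120.0,
        school_dispersion_m=200.0,
    )
    return generate_world(cfg)
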