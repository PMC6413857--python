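"""Exact network distances from outlets to their nearest outlet and school.

POIs are materialised as graph nodes by splitting their snapped edge at the
exact arc offset, so distances are measured point-to-point along the streets
with no up-to-one-edge-length discretisation error.  Nearest-school queries
run one multi-source Dijkstra (equivalent to a virtual zero-weight source
attached to every school node); nearest-other-outlet queries run one
early-terminating Dijkstra per outlet.  Euclidean ("as the crow flies")
counterparts come from an exact KD-tree.  All distances stay within one
district's graph, mirroring the per-district processing of the analysis;
cross-district proximity is a documented limitation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import LineString
from shapely.ops import substring as _substring

from .geo_core import Point, Polyline
from .network_builder import Edge, StreetGraph
from .poi_assignment import SnapResult
from . import _graphalg

logger = logging.getLogger(__name__)

#: co-location tolerance in meters: snap points closer than this share a node.
CO_LOCATION_TOL = 1e-6

#: default buffer grid: zoning policies in England use up to 600 m.
DEFAULT_BIN_EDGES = tuple(float(x) for x in range(0, 601, 60))


@dataclass
class SnappedNetwork:
    """Street graph augmented with one node per snapped POI."""

    graph: StreetGraph
    poi_nodes: dict[str, int]

    def csr(self):
        if not hasattr(self, "_csr"):
            self._csr = self.graph.to_csr()[:3]
        return self._csr


@dataclass
class DistanceRecord:
    """Nearest-entity distances for one outlet, network and Euclidean."""

    poi_id: str
    nearest_outlet_net_m: float
    nearest_school_net_m: float
    nearest_outlet_euc_m: float
    nearest_school_euc_m: float
    tertile: int = 0


@dataclass
class BufferCurve:
    """Histogram of distances over a policy-buffer grid.

    Bins are ``(prev_edge, edge]`` plus a dedicated spike bin for exact-zero
    distances and an overflow bin past the last edge.  ``fraction_within``
    gives the cumulative fraction of (finite-distance) outlets at each edge.
    """

    bin_edges: tuple[float, ...]
    zero_count: int
    bin_counts: tuple[int, ...]
    overflow_count: int
    n_infinite: int

    @property
    def n_finite(self) -> int:
        return self.zero_count + sum(self.bin_counts) + self.overflow_count

    @property
    def fraction_within(self) -> tuple[float, ...]:
        """Cumulative fraction at each bin edge (edge 0 captures the zeros)."""
        n = self.n_finite
        cum = self.zero_count
        out = []
        for i, edge in enumerate(self.bin_edges):
            if i > 0:
                cum += self.bin_counts[i - 1]
            out.append(cum / n)
        return tuple(out)

    def capture_at(self, distance: float) -> float:
        """Cumulative fraction at the largest bin edge <= ``distance``."""
        fw = self.fraction_within
        idx = max(i for i, e in enumerate(self.bin_edges) if e <= distance)
        return fw[idx]


# ---------------------------------------------------------------------------
# snap-node insertion


def insert_snap_nodes(graph: StreetGraph, snaps: Sequence[SnapResult]) -> SnappedNetwork:
    """Split each snapped edge at its snap offsets; return the new network.

    Snap points within :data:`CO_LOCATION_TOL` of each other (or of an edge
    endpoint) share one node.  Child edge lengths are consecutive offset
    differences, so total length is conserved exactly.
    """
    g = StreetGraph(
        district_id=graph.district_id,
        nodes=dict(graph.nodes),
        edges={eid: replace(e) for eid, e in graph.edges.items()},
    )
    poi_nodes: dict[str, int] = {}
    by_edge: dict[int, list[SnapResult]] = {}
    for s in snaps:
        by_edge.setdefault(s.edge_id, []).append(s)
    next_nid = max(g.nodes, default=-1) + 1
    next_eid = max(g.edges, default=-1) + 1

    for eid in sorted(by_edge):
        edge = g.edges[eid]
        length = edge.length
        items = sorted(by_edge[eid], key=lambda s: (s.offset_t, s.poi_id))
        # cluster snap offsets; reuse endpoint nodes at the edge extremes
        cuts: list[tuple[float, int]] = []  # (arc offset m, node id)
        for s in items:
            arc = min(max(s.offset_t, 0.0), 1.0) * length
            if arc <= CO_LOCATION_TOL:
                poi_nodes[s.poi_id] = edge.u
                continue
            if arc >= length - CO_LOCATION_TOL:
                poi_nodes[s.poi_id] = edge.v
                continue
            if cuts and arc - cuts[-1][0] <= CO_LOCATION_TOL:
                poi_nodes[s.poi_id] = cuts[-1][1]
                continue
            line = LineString(edge.geometry.points)
            pt = line.interpolate(arc)
            g.nodes[next_nid] = Point(pt.x, pt.y)
            cuts.append((arc, next_nid))
            poi_nodes[s.poi_id] = next_nid
            next_nid += 1
        if not cuts:
            continue
        line = LineString(edge.geometry.points)
        bounds = [(0.0, edge.u)] + cuts + [(length, edge.v)]
        del g.edges[eid]
        for (a0, u), (a1, v) in zip(bounds, bounds[1:]):
            piece = _substring(line, a0, a1)
            geom_pts = [Point(x, y) for x, y in piece.coords]
            dedup = [geom_pts[0]]
            for q in geom_pts[1:]:
                if q != dedup[-1]:
                    dedup.append(q)
            if len(dedup) < 2:
                dedup = [g.nodes[u], g.nodes[v]]
            g.edges[next_eid] = Edge(
                u=u, v=v, length=a1 - a0, geometry=Polyline(dedup),
                segment_id=edge.segment_id, lsoa_ids=edge.lsoa_ids,
                imd=edge.imd, tertile=edge.tertile,
            )
            next_eid += 1
    return SnappedNetwork(graph=g, poi_nodes=poi_nodes)


# ---------------------------------------------------------------------------
# shortest-path queries


def dijkstra(network: SnappedNetwork | StreetGraph, source_node: int) -> np.ndarray:
    """Exact single-source shortest-path distances (inf when unreachable)."""
    g = network.graph if isinstance(network, SnappedNetwork) else network
    indptr, indices, weights, _ = g.to_csr()
    return _graphalg.sssp(indptr, indices, weights,
                          np.array([source_node], dtype=np.int64))


def nearest_school_distances(
    network: SnappedNetwork,
    school_nodes: Mapping[str, int] | Sequence[int],
    outlet_nodes: Mapping[str, int],
) -> dict[str, float]:
    """Per outlet, network distance to the closest school.

    One multi-source Dijkstra from all school nodes (a virtual source with
    zero-weight arcs to each school); equals the minimum over per-school
    single-source runs.
    """
    sources = (
        list(school_nodes.values()) if isinstance(school_nodes, Mapping)
        else list(school_nodes)
    )
    if not sources:
        raise ValueError("need at least one school")
    indptr, indices, weights = network.csr()
    dist = _graphalg.sssp(indptr, indices, weights, np.array(sorted(set(sources)), dtype=np.int64))
    out: dict[str, float] = {}
    for pid, node in outlet_nodes.items():
        d = float(dist[node])
        if not np.isfinite(d):
            logger.warning("outlet %s: no school reachable", pid)
        out[pid] = d
    return out


def nearest_other_outlet_distances(
    network: SnappedNetwork, outlet_nodes: Mapping[str, int]
) -> dict[str, float]:
    """Per outlet, network distance to the closest *other* outlet.

    Outlets sharing a node are at distance 0; otherwise Dijkstra terminates
    on the first settled other-outlet node.
    """
    if len(outlet_nodes) < 2:
        raise ValueError("need at least two outlets")
    indptr, indices, weights = network.csr()
    n = network.graph.n
    is_target = np.zeros(n, dtype=np.uint8)
    occupancy = np.zeros(n, dtype=np.int64)
    for node in outlet_nodes.values():
        is_target[node] = 1
        occupancy[node] += 1
    out: dict[str, float] = {}
    for pid, node in outlet_nodes.items():
        if occupancy[node] >= 2:
            out[pid] = 0.0
        else:
            out[pid] = float(
                _graphalg.dijkstra_nearest(indptr, indices, weights, node, is_target)
            )
    return out


def euclidean_nearest(
    points: np.ndarray, targets: np.ndarray, exclude_self: bool = False
) -> np.ndarray:
    """Exact straight-line nearest-target distance for each point.

    With ``exclude_self`` each point is assumed to be one of ``targets`` (by
    index alignment) and its own entry is skipped; co-located distinct
    targets still yield 0.
    """
    from scipy.spatial import cKDTree

    points = np.asarray(points, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(targets) == 0:
        raise ValueError("targets must be non-empty")
    tree = cKDTree(targets)
    if not exclude_self:
        d, _ = tree.query(points, k=1)
        return np.asarray(d, dtype=float)
    if len(targets) < 2:
        raise ValueError("exclude_self needs at least two targets")
    d, idx = tree.query(points, k=2)
    out = np.where(idx[:, 0] == np.arange(len(points)), d[:, 1], d[:, 0])
    return np.asarray(out, dtype=float)


# ---------------------------------------------------------------------------
# buffer-capture curves


def buffer_curve(
    distances, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> BufferCurve:
    """Histogram distances over ``bin_edges`` with a zero spike + overflow.

    Infinite distances are excluded from the curve and reported in
    ``n_infinite``.
    """
    d = np.asarray(list(distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances")
    if np.any(d < 0):
        raise ValueError("negative distance")
    edges = [float(e) for e in bin_edges]
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin edges must be strictly increasing")
    inf_mask = ~np.isfinite(d)
    d = d[~inf_mask]
    if d.size == 0:
        raise ValueError("all distances infinite")
    zero = int(np.sum(d == 0.0))
    pos = d[d > 0.0]
    counts = []
    for lo, hi in zip(edges, edges[1:]):
        counts.append(int(np.sum((pos > lo) & (pos <= hi))))
    counts[0] += int(np.sum(pos <= edges[0]))  # sub-first-edge positives
    overflow = int(np.sum(pos > edges[-1]))
    return BufferCurve(
        bin_edges=tuple(edges),
        zero_count=zero,
        bin_counts=tuple(counts),
        overflow_count=overflow,
        n_infinite=int(np.sum(inf_mask)),
    )
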