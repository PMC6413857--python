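"""Overlay small-area (LSOA-like) polygons and deprivation scores on edges.

Stages 4-5: each edge is assigned the small area(s) it lies in -- edges
spanning two areas are split at the boundary exactly as roads were split
across districts, edges coincident with a shared area boundary are assigned
to both -- then every edge receives a deprivation score (its area's score,
or the mean of the two) and a tertile label.

Tertile boundaries are empirical order statistics: with ``n`` sorted scores,
``q1`` is the ``ceil(n/3)``-th and ``q2`` the ``ceil(2n/3)``-th value, and
upper boundaries are inclusive (a score exactly equal to ``q1`` falls in
tertile 1).  Counts per tertile then differ by at most the remainder of
``n/3``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString
from shapely.strtree import STRtree

from .geo_core import Point, Polygon, Polyline, clip_polyline
from .network_builder import Edge, StreetGraph, _weld_key
from .poi_assignment import SnapResult

logger = logging.getLogger(__name__)

#: relative coverage above which an edge counts as lying along a boundary /
#: inside an area (guards float dust from exact shapely cuts).
_COVER_RTOL = 1e-9


class DegenerateTertilesError(ValueError):
    """All scores identical: tertile boundaries are undefined."""


@dataclass
class AreaUnit:
    """Small-area polygon carrying a continuous deprivation score."""

    id: str
    geometry: Polygon
    imd_score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.imd_score):
            raise ValueError(f"area {self.id}: non-finite deprivation score")


@dataclass
class DeprivationTertiles:
    """Tertile boundaries (inclusive upper bounds) and per-tertile counts."""

    q1: float
    q2: float
    counts: tuple[int, int, int]

    def label(self, score: float) -> int:
        if score <= self.q1:
            return 1
        if score <= self.q2:
            return 2
        return 3


def compute_tertiles(scores) -> DeprivationTertiles:
    """Empirical tertiles of ``scores`` with inclusive upper boundaries."""
    s = np.sort(np.asarray(list(scores), dtype=float))
    n = len(s)
    if n < 3:
        raise ValueError(f"need >= 3 scores, got {n}")
    if s[0] == s[-1]:
        raise DegenerateTertilesError("all deprivation scores are equal")
    q1 = float(s[math.ceil(n / 3) - 1])
    q2 = float(s[math.ceil(2 * n / 3) - 1])
    c1 = int(np.sum(s <= q1))
    c2 = int(np.sum((s > q1) & (s <= q2)))
    c3 = n - c1 - c2
    return DeprivationTertiles(q1=q1, q2=q2, counts=(c1, c2, c3))


# ---------------------------------------------------------------------------
# area assignment (with edge splitting)


def _split_edge(
    graph: StreetGraph,
    eid: int,
    pieces: list[tuple[float, Polyline, str]],
    next_eid: int,
    next_nid: int,
    node_of: dict,
) -> tuple[dict[int, str], int, int]:
    """Replace edge ``eid`` by one child edge per (arc-sorted) piece.

    Returns (child edge id -> area id, next_eid, next_nid).  Child lengths
    sum to the parent length because cut points are exact intersections.
    """
    parent = graph.edges.pop(eid)
    pieces = sorted(pieces, key=lambda t: t[0])
    assignment: dict[int, str] = {}

    def node_for(p: Point) -> int:
        nonlocal next_nid
        key = _weld_key(p)
        if key not in node_of:
            node_of[key] = next_nid
            graph.nodes[next_nid] = p
            next_nid += 1
        return node_of[key]

    for k, (_, geom, area_id) in enumerate(pieces):
        u = parent.u if k == 0 else node_for(geom.points[0])
        v = parent.v if k == len(pieces) - 1 else node_for(geom.points[-1])
        graph.edges[next_eid] = Edge(
            u=u, v=v, length=geom.length(), geometry=geom,
            segment_id=parent.segment_id,
        )
        assignment[next_eid] = area_id
        next_eid += 1
    return assignment, next_eid, next_nid


def assign_areas_to_edges(
    graph: StreetGraph,
    areas: list[AreaUnit],
    snaps: list[SnapResult] | None = None,
) -> dict[int, tuple[str, ...]]:
    """Assign each edge its area(s), splitting edges that span two areas.

    Mutates ``graph``: spanning edges are replaced by child edges (lengths
    conserved); returns edge id -> tuple of one or two area ids.  Edges
    outside every area are logged and attached to the nearest area.  When
    ``snaps`` is given, POIs snapped to a split edge are re-attached to the
    child edge containing their arc offset.
    """
    shapes = [a.geometry.to_shapely() for a in areas]
    tree = STRtree(shapes)
    node_of = {_weld_key(p): i for i, p in graph.nodes.items()}
    next_eid = max(graph.edges, default=-1) + 1
    next_nid = max(graph.nodes, default=-1) + 1
    assignment: dict[int, tuple[str, ...]] = {}
    parent_children: dict[int, list[tuple[int, float, float]]] = {}

    for eid in sorted(graph.edges):
        edge = graph.edges[eid]
        line = LineString(edge.geometry.points)
        cand = tree.query(line)
        on_boundary: list[str] = []
        covering: list[int] = []
        partial: list[int] = []
        for ci in sorted(cand):
            inter = line.intersection(shapes[ci])
            if inter.is_empty or inter.length <= 1e-9:
                continue
            blen = line.intersection(shapes[ci].boundary).length
            if blen >= line.length * (1 - 1e-9):
                on_boundary.append(areas[ci].id)
            elif inter.length >= line.length * (1 - _COVER_RTOL):
                covering.append(ci)
            else:
                partial.append(ci)

        if on_boundary:
            assignment[eid] = tuple(sorted(on_boundary)[:2])
        elif len(covering) == 1 and not partial:
            assignment[eid] = (areas[covering[0]].id,)
        elif partial or len(covering) > 1:
            pieces: list[tuple[float, Polyline, str]] = []
            for ci in partial + covering:
                for piece in clip_polyline(edge.geometry, areas[ci].geometry):
                    if piece.relation != "inside":
                        continue
                    arc = line.project(
                        LineString(piece.geometry.points).interpolate(0.5, normalized=True)
                    )
                    pieces.append((float(arc), piece.geometry, areas[ci].id))
            if not pieces:
                assignment[eid] = _nearest_area(edge, areas)
                continue
            child_map, next_eid, next_nid = _split_edge(
                graph, eid, pieces, next_eid, next_nid, node_of
            )
            arc0 = 0.0
            children = []
            for ceid in sorted(child_map):
                clen = graph.edges[ceid].length
                children.append((ceid, arc0, arc0 + clen))
                arc0 += clen
                assignment[ceid] = (child_map[ceid],)
            parent_children[eid] = children
        else:
            assignment[eid] = _nearest_area(edge, areas)

    if snaps is not None:
        for snap in snaps:
            children = parent_children.get(snap.edge_id)
            if children is None:
                continue
            total = children[-1][2]
            s = snap.offset_t * total
            for ceid, a0, a1 in children:
                if s <= a1 + 1e-12 or ceid == children[-1][0]:
                    snap.edge_id = ceid
                    snap.offset_t = min(1.0, max(0.0, (s - a0) / (a1 - a0)))
                    break
    return assignment


def _nearest_area(edge: Edge, areas: list[AreaUnit]) -> tuple[str, ...]:
    mid = LineString(edge.geometry.points).interpolate(0.5, normalized=True)
    best = min(areas, key=lambda a: a.geometry.to_shapely().distance(mid))
    logger.warning("edge %s outside all areas: attached to nearest area %s",
                   edge.segment_id, best.id)
    return (best.id,)


def assign_imd(
    graph: StreetGraph,
    assignment: dict[int, tuple[str, ...]],
    areas: list[AreaUnit],
) -> dict[int, float]:
    """Write each edge's deprivation score: its area's score, or the mean of
    the two scores for boundary edges."""
    score_of = {a.id: a.imd_score for a in areas}
    out: dict[int, float] = {}
    for eid, area_ids in assignment.items():
        if eid not in graph.edges:
            continue
        score = float(np.mean([score_of[aid] for aid in area_ids]))
        graph.edges[eid].imd = score
        graph.edges[eid].lsoa_ids = tuple(area_ids)
        out[eid] = score
    return out


def label_edges(graph: StreetGraph, tertiles: DeprivationTertiles) -> None:
    """Stamp each edge with its deprivation tertile (1, 2 or 3)."""
    for edge in graph.edges.values():
        if math.isfinite(edge.imd):
            edge.tertile = tertiles.label(edge.imd)
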