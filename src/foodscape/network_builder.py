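"""Build per-district street graphs from raw road polylines.

Stage 1-2 of the pipeline: every road polyline is assigned to the district(s)
it lies in -- whole when fully inside, cut at every boundary intersection when
crossing, duplicated to both districts when coincident with a shared border --
and each district's segments are welded into an undirected weighted graph
(one edge per segment, weight = length in meters).  A diagnosis step then
classifies disconnection pathologies (detached hamlet, critical connector road
administratively in the neighbouring district, island groups) and a resolution
step applies one of three strategies: re-assign the bridging segment, split
the district per component, or drop the district.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .geo_core import (
    ClipPiece,
    Point,
    Polygon,
    Polyline,
    clip_polyline,
    polyline_length,
)
from . import _graphalg

logger = logging.getLogger(__name__)

#: node welding tolerance in meters: boundary cut points computed by clipping
#: must weld exactly, so this sits far below the geometry scale.
SNAP_TOL = 1e-6

#: a connected component holding less than this fraction of nodes is "small".
SMALL_COMPONENT_FRAC = 0.05


class DistrictDataError(ValueError):
    """Inconsistent district geometry (e.g. overlapping polygons)."""


class StrategyError(ValueError):
    """Resolution strategy inapplicable to the diagnosed archetype."""


@dataclass
class RoadSegment:
    """A polyline piece assigned to one district (or two, on a shared border)."""

    id: str
    district_ids: tuple[str, ...]
    geometry: Polyline
    length: float
    parent_road_id: str

    def __post_init__(self) -> None:
        if not 1 <= len(self.district_ids) <= 2:
            raise ValueError(f"segment {self.id}: needs 1 or 2 districts")


@dataclass
class Edge:
    """Graph edge: one road segment with the attributes later stages add."""

    u: int
    v: int
    length: float
    geometry: Polyline
    segment_id: str
    outlet_count: int = 0
    school_count: int = 0
    lsoa_ids: tuple[str, ...] = ()
    imd: float = float("nan")
    tertile: int = 0


@dataclass
class StreetGraph:
    """Undirected weighted street graph of one district.

    ``nodes`` maps node id -> coordinates; ``edges`` maps edge id ->
    :class:`Edge`.  Edge ids are dense ints assigned in input order, which is
    what downstream deterministic tie-breaking relies on.
    """

    district_id: str
    nodes: dict[int, Point] = field(default_factory=dict)
    edges: dict[int, Edge] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.edges)

    def node_order(self) -> list[int]:
        """Node ids in the dense positional order used by array algorithms."""
        return sorted(self.nodes)

    def node_xy(self) -> np.ndarray:
        return np.array([self.nodes[i] for i in self.node_order()], dtype=float)

    def to_csr(self):
        """CSR adjacency (both arc directions) plus the dense edge-id order.

        Node ids are remapped to positions in :meth:`node_order`, so the
        arrays stay valid for subgraphs with gaps in their id space.
        """
        pos = {nid: i for i, nid in enumerate(self.node_order())}
        eids = sorted(self.edges)
        u = np.array([pos[self.edges[e].u] for e in eids], dtype=np.int64)
        v = np.array([pos[self.edges[e].v] for e in eids], dtype=np.int64)
        w = np.array([self.edges[e].length for e in eids], dtype=float)
        indptr, indices, weights, arc_eid = _graphalg.build_csr(self.n, u, v, w)
        return indptr, indices, weights, np.array(eids, dtype=np.int64)[arc_eid]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, p in self.nodes.items():
            g.add_node(i, x=p.x, y=p.y)
        for e, edge in self.edges.items():
            # parallel edges collapse to the shorter one; fine for connectivity
            if g.has_edge(edge.u, edge.v) and g[edge.u][edge.v]["weight"] <= edge.length:
                continue
            g.add_edge(edge.u, edge.v, weight=edge.length, edge_id=e)
        return g


@dataclass
class ConnectivityDiagnosis:
    """Connected components of a district graph and the pathology archetype."""

    district_id: str
    components: list[set[int]]
    unreachable_pois: list[str]
    archetype: str  # hamlet | boundary_connector | islands | none


# ---------------------------------------------------------------------------
# step 1-2: assignment and graph construction


def _weld_key(p: Point, tol: float = SNAP_TOL) -> tuple[int, int]:
    return (round(p.x / tol), round(p.y / tol))


def _bbox(points: Sequence[Point]) -> tuple[float, float, float, float]:
    xs = [p.x for p in points]
    ys = [p.y for p in points]
    return min(xs), min(ys), max(xs), max(ys)


def _bbox_overlap(a, b, pad: float = SNAP_TOL) -> bool:
    return not (a[2] < b[0] - pad or b[2] < a[0] - pad or a[3] < b[1] - pad or b[3] < a[1] - pad)


def check_districts_disjoint(districts: Sequence[Polygon], area_tol: float = 1e-6) -> None:
    """Raise when two district polygons overlap beyond a shared boundary."""
    for i in range(len(districts)):
        for j in range(i + 1, len(districts)):
            inter = districts[i].to_shapely().intersection(districts[j].to_shapely())
            if inter.area > area_tol:
                raise DistrictDataError(
                    f"districts {districts[i].id!r} and {districts[j].id!r} overlap "
                    f"(area {inter.area:.3g} m^2)"
                )


def assign_roads_to_districts(
    roads: Sequence[Polyline], districts: Sequence[Polygon]
) -> list[RoadSegment]:
    """Assign every road polyline to the district(s) containing it.

    Fully-inside roads keep their geometry; crossing roads are cut at every
    boundary intersection and each inside piece goes to its district; pieces
    coincident with a shared border are emitted once with both district ids;
    fully-outside roads (or outside remainders) are discarded.
    """
    check_districts_disjoint(districts)
    district_boxes = [_bbox(d.exterior) for d in districts]
    segments: list[RoadSegment] = []
    # boundary pieces keyed by geometry so the two adjacent districts merge
    boundary_pieces: dict[tuple, tuple[ClipPiece, set[str]]] = {}

    for road in roads:
        rbox = _bbox(road.points)
        for dist, dbox in zip(districts, district_boxes):
            if not _bbox_overlap(rbox, dbox):
                continue
            for piece in clip_polyline(road, dist):
                if piece.relation == "boundary":
                    key = (road.id, tuple(_weld_key(p) for p in piece.geometry.points))
                    rkey = (road.id, tuple(reversed(key[1])))
                    hit = boundary_pieces.get(key) or boundary_pieces.get(rkey)
                    if hit is None:
                        boundary_pieces[key] = (piece, {dist.id})
                    else:
                        hit[1].add(dist.id)
                else:
                    seg_id = f"{road.id}@{dist.id}.{len(segments)}"
                    segments.append(
                        RoadSegment(
                            id=seg_id,
                            district_ids=(dist.id,),
                            geometry=piece.geometry,
                            length=polyline_length(piece.geometry),
                            parent_road_id=road.id,
                        )
                    )

    for k, (piece, dids) in enumerate(boundary_pieces.values()):
        segments.append(
            RoadSegment(
                id=f"{piece.parent_id}@border.{k}",
                district_ids=tuple(sorted(dids))[:2],
                geometry=piece.geometry,
                length=polyline_length(piece.geometry),
                parent_road_id=piece.parent_id,
            )
        )
    return segments


def build_graph(
    segments: Iterable[RoadSegment], district_id: str, tol: float = SNAP_TOL
) -> StreetGraph:
    """Weld segments of one district into a :class:`StreetGraph`.

    Nodes are deduplicated by coordinate within ``tol``; each segment becomes
    one edge weighted by its length.  Zero-length segments are rejected with a
    warning rather than an exception.
    """
    g = StreetGraph(district_id=district_id)
    node_of: dict[tuple[int, int], int] = {}

    def get_node(p: Point) -> int:
        key = _weld_key(p, tol)
        if key not in node_of:
            node_of[key] = len(node_of)
            g.nodes[node_of[key]] = p
        return node_of[key]

    eid = 0
    for seg in segments:
        if district_id not in seg.district_ids:
            continue
        if seg.length <= tol:
            logger.warning("district %s: rejecting zero-length segment %s", district_id, seg.id)
            continue
        u = get_node(seg.geometry.points[0])
        v = get_node(seg.geometry.points[-1])
        g.edges[eid] = Edge(u=u, v=v, length=seg.length, geometry=seg.geometry, segment_id=seg.id)
        eid += 1
    return g


# ---------------------------------------------------------------------------
# connectivity diagnosis


def _component_gap(g: StreetGraph, comp_a: set[int], comp_b: set[int]) -> float:
    xy_a = np.array([g.nodes[i] for i in comp_a], dtype=float)
    xy_b = np.array([g.nodes[i] for i in comp_b], dtype=float)
    d, _ = cKDTree(xy_b).query(xy_a, k=1)
    return float(np.min(d))


def _long_edge_length(g: StreetGraph) -> float:
    """95th-percentile edge length: a robust proxy for the block/grid pitch
    (the median would be dragged down by short bend-induced segments)."""
    if not g.edges:
        return 0.0
    return float(np.percentile([e.length for e in g.edges.values()], 95))


def diagnose_connectivity(
    g: StreetGraph,
    poi_edges: Mapping[str, int] | None = None,
    small_frac: float = SMALL_COMPONENT_FRAC,
    near_gap: float | None = None,
) -> ConnectivityDiagnosis:
    """List connected components, flag unreachable POIs, classify archetype.

    ``poi_edges`` maps poi id -> snapped edge id; a POI is unreachable when
    its edge lies outside the largest component.  Archetypes: ``hamlet`` (one
    main component plus small detached ones), ``boundary_connector`` (two
    large components whose hulls nearly touch -- within ``near_gap``, default
    twice the 95th-percentile edge length, a proxy for the block pitch),
    ``islands`` (several large, mutually distant components).
    """
    comps = sorted(nx.connected_components(g.to_networkx()), key=len, reverse=True)
    comps = [set(c) for c in comps]
    unreachable: list[str] = []
    if poi_edges and comps:
        main = comps[0]
        for pid, eid in poi_edges.items():
            e = g.edges[eid]
            if e.u not in main and e.v not in main:
                unreachable.append(pid)

    if len(comps) <= 1:
        archetype = "none"
    else:
        if near_gap is None:
            near_gap = 2.0 * _long_edge_length(g)
        large = [c for c in comps if len(c) >= small_frac * g.n]
        if len(large) >= 3:
            archetype = "islands"
        elif len(large) == 2:
            gap = _component_gap(g, large[0], large[1])
            archetype = "boundary_connector" if gap < near_gap else "islands"
        else:
            archetype = "hamlet"
    return ConnectivityDiagnosis(
        district_id=g.district_id,
        components=comps,
        unreachable_pois=sorted(unreachable),
        archetype=archetype,
    )


# ---------------------------------------------------------------------------
# resolution


def resolve_disconnection(
    districts: Sequence[Polygon],
    segments: Sequence[RoadSegment],
    diagnosis: ConnectivityDiagnosis,
    strategy: str,
) -> tuple[list[Polygon], list[RoadSegment]]:
    """Resolve a diagnosed pathology; returns updated (districts, segments).

    * ``reassign_connector`` -- move the minimal foreign segment that bridges
      the two large components into this district (the road was
      administratively across the border).
    * ``split_district`` -- one new district entry per component.
    * ``drop_district`` -- remove the district and its exclusive segments.
    """
    if diagnosis.archetype == "none":
        raise StrategyError("nothing to resolve: archetype is 'none'")
    did = diagnosis.district_id
    applicable = {
        "reassign_connector": ("boundary_connector",),
        "split_district": ("hamlet", "boundary_connector", "islands"),
        "drop_district": ("hamlet", "boundary_connector", "islands"),
    }
    if strategy not in applicable:
        raise StrategyError(f"unknown strategy {strategy!r}")
    if diagnosis.archetype not in applicable[strategy]:
        raise StrategyError(f"{strategy} inapplicable to archetype {diagnosis.archetype!r}")

    if strategy == "drop_district":
        new_districts = [d for d in districts if d.id != did]
        new_segments = []
        for s in segments:
            if did in s.district_ids:
                rest = tuple(x for x in s.district_ids if x != did)
                if not rest:
                    continue
                s = replace(s, district_ids=rest)
            new_segments.append(s)
        return new_districts, new_segments

    g = build_graph(segments, did)
    if strategy == "reassign_connector":
        large = sorted(diagnosis.components, key=len, reverse=True)[:2]
        comp_of: dict[tuple[int, int], int] = {}
        for ci, comp in enumerate(large):
            for node in comp:
                comp_of[_weld_key(g.nodes[node])] = ci
        best: RoadSegment | None = None
        for s in segments:
            if did in s.district_ids:
                continue
            ka = comp_of.get(_weld_key(s.geometry.points[0]))
            kb = comp_of.get(_weld_key(s.geometry.points[-1]))
            if ka is not None and kb is not None and ka != kb:
                if best is None or s.length < best.length:
                    best = s
        if best is None:
            raise StrategyError(f"district {did}: no bridging segment found in neighbours")
        new_segments = [
            replace(s, district_ids=(did,)) if s.id == best.id else s for s in segments
        ]
        logger.info("district %s: re-assigned connector %s (%.1f m) from %s",
                    did, best.id, best.length, best.district_ids)
        return list(districts), new_segments

    # split_district: partition this district's segments by component
    key_to_comp: dict[tuple[int, int], int] = {}
    for ci, comp in enumerate(diagnosis.components):
        for node in comp:
            key_to_comp[_weld_key(g.nodes[node])] = ci
    part_ids = [f"{did}/part{ci}" for ci in range(len(diagnosis.components))]
    new_segments = []
    for s in segments:
        if did in s.district_ids:
            ci = key_to_comp.get(_weld_key(s.geometry.points[0]), 0)
            new_ids = tuple(part_ids[ci] if x == did else x for x in s.district_ids)
            s = replace(s, district_ids=new_ids)
        new_segments.append(s)
    src = next(d for d in districts if d.id == did)
    new_districts = [d for d in districts if d.id != did]
    for ci, pid in enumerate(part_ids):
        new_districts.append(
            Polygon(list(src.exterior), [list(h) for h in src.holes], id=pid,
                    name=f"{src.name or did} (part {ci})")
        )
    return new_districts, new_segments
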