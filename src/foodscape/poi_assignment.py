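"""Filter POI records, resolve their district, and snap each to a segment.

Stage 3: raw point-of-interest records (fast-food outlets, category code
``0018``; schools, category code ``31``) are filtered for completeness,
linked to a district through their district code -- with an explicit
many-to-one name map standing in for manual geolocation of county-named
codes -- and assigned to the nearest road segment of that district.

Snapping is defined by the exhaustive minimum over all of the district's
edges; a KD-tree over sub-segment midpoints only accelerates the search and
must return the identical (exact) result.  Ties break on the smallest edge
id, so results are deterministic and seed-independent.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geo_core import Point, Polygon
from .network_builder import StreetGraph

logger = logging.getLogger(__name__)

#: raw source category codes -> pipeline categories
CATEGORY_CODES = {"0018": "outlet", "31": "school"}


class DistrictNameError(ValueError):
    """Two districts share a name: district codes cannot be resolved."""


@dataclass
class PoiRecord:
    """One point of interest: an outlet, a school, or anything else."""

    id: str
    category: str  # outlet | school | other (raw codes are normalized)
    location: Point
    postal_code: str = ""
    district_code: str = ""

    def __post_init__(self) -> None:
        self.category = CATEGORY_CODES.get(self.category, self.category)
        if self.category not in ("outlet", "school"):
            self.category = "other"
        self.location = Point(float(self.location[0]), float(self.location[1]))


@dataclass
class SnapResult:
    """Assignment of a POI to its nearest edge.

    ``offset_t`` is the arc-length fraction of the foot point along the full
    edge polyline, which is what exact snap-node insertion needs.
    """

    poi_id: str
    edge_id: int
    snap_distance: float
    offset_t: float


def filter_pois(records: Iterable[PoiRecord]) -> tuple[list[PoiRecord], dict[str, int]]:
    """Keep complete outlet/school records; tally discards per reason.

    A record is discarded when its postal code or district code is blank, or
    when its category is neither outlet nor school.
    """
    kept: list[PoiRecord] = []
    discarded: Counter[str] = Counter()
    for rec in records:
        if rec.category not in ("outlet", "school"):
            discarded["other_category"] += 1
        elif not rec.district_code.strip():
            discarded["missing_district"] += 1
        elif not rec.postal_code.strip():
            discarded["missing_postal"] += 1
        else:
            kept.append(rec)
    return kept, dict(discarded)


def resolve_district(
    record: PoiRecord,
    districts: Sequence[Polygon],
    name_map: Mapping[str, str] | None = None,
) -> str | None:
    """Map a record's district code to a district id.

    An exact match on district name (or id) wins; otherwise the explicit
    many-to-one ``name_map`` (code -> district id) is consulted.  Unresolved
    records return ``None`` and are logged.  Duplicate district names raise
    :class:`DistrictNameError`.
    """
    by_name: dict[str, str] = {}
    ids = {d.id for d in districts}
    for d in districts:
        if d.name:
            if d.name in by_name and by_name[d.name] != d.id:
                raise DistrictNameError(f"two districts named {d.name!r}")
            by_name[d.name] = d.id
    code = record.district_code.strip()
    if code in by_name:
        return by_name[code]
    if code in ids:
        return code
    if name_map and code in name_map:
        target = name_map[code]
        if target in ids:
            return target
        logger.warning("poi %s: name_map target %r is not a district", record.id, target)
        return None
    logger.warning("poi %s: unresolved district code %r", record.id, code)
    return None


# ---------------------------------------------------------------------------
# snapping


class _EdgeIndex:
    """Exact nearest-edge index over a district's edge polylines.

    Every polyline is decomposed into its straight sub-segments; a KD-tree on
    sub-segment midpoints bounds the search radius, then candidate
    sub-segments are scanned exhaustively, so the reported minimum equals the
    brute-force scan over all edges.
    """

    def __init__(self, graph: StreetGraph):
        if graph.m == 0:
            raise ValueError(f"district {graph.district_id}: empty graph")
        eids, seg_a, seg_b, arc0, half = [], [], [], [], []
        for eid in sorted(graph.edges):
            e = graph.edges[eid]
            pts = e.geometry.points
            arc = 0.0
            for aa, bb in zip(pts, pts[1:]):
                eids.append(eid)
                seg_a.append(aa)
                seg_b.append(bb)
                arc0.append(arc)
                arc += float(np.hypot(bb.x - aa.x, bb.y - aa.y))
            half.append(arc)
        self.eid = np.array(eids, dtype=np.int64)
        self.a = np.array(seg_a, dtype=float)
        self.b = np.array(seg_b, dtype=float)
        self.arc0 = np.array(arc0, dtype=float)
        self.edge_len = {eid: graph.edges[eid].length for eid in graph.edges}
        self.seg_len = np.hypot(*(self.b - self.a).T)
        self.mid = (self.a + self.b) / 2
        self.tree = cKDTree(self.mid)
        self.max_half = float(np.max(self.seg_len)) / 2

    def _exact_among(self, p: Point, idx: np.ndarray) -> tuple[float, int, float]:
        """Exact minimum over sub-segments ``idx``; smallest edge id wins ties."""
        ax, ay = self.a[idx, 0], self.a[idx, 1]
        dx, dy = self.b[idx, 0] - ax, self.b[idx, 1] - ay
        seg2 = dx * dx + dy * dy
        t = np.clip(((p[0] - ax) * dx + (p[1] - ay) * dy) / seg2, 0.0, 1.0)
        dist = np.hypot(p[0] - (ax + t * dx), p[1] - (ay + t * dy))
        dmin = dist.min()
        tie = np.flatnonzero(dist <= dmin + 1e-12)
        # among tied sub-segments, the smallest edge id wins
        pick = tie[np.argmin(self.eid[idx][tie])]
        eid = int(self.eid[idx][pick])
        arc = float(self.arc0[idx][pick] + t[pick] * self.seg_len[idx][pick])
        return float(dist[pick]), eid, arc / self.edge_len[eid]

    def nearest(self, p: Point) -> tuple[float, int, float]:
        d0, _ = self.tree.query([p[0], p[1]], k=1)
        radius = d0 + self.max_half + 1e-9
        idx = np.array(self.tree.query_ball_point([p[0], p[1]], r=radius), dtype=np.int64)
        return self._exact_among(p, idx)

    def nearest_bruteforce(self, p: Point) -> tuple[float, int, float]:
        return self._exact_among(p, np.arange(len(self.eid)))


def snap_to_edge(
    poi: PoiRecord, graph: StreetGraph, index: _EdgeIndex | None = None
) -> SnapResult:
    """Snap ``poi`` to the edge of ``graph`` minimizing point-to-segment
    distance (global minimum; ties broken by smallest edge id)."""
    if index is None:
        index = _EdgeIndex(graph)
    dist, eid, t = index.nearest(poi.location)
    return SnapResult(poi_id=poi.id, edge_id=eid, snap_distance=dist, offset_t=t)


def snap_all(pois: Sequence[PoiRecord], graph: StreetGraph) -> list[SnapResult]:
    """Snap many POIs to one district graph, sharing the spatial index."""
    index = _EdgeIndex(graph)
    return [snap_to_edge(p, graph, index) for p in pois]


def count_per_edge(
    snaps: Iterable[SnapResult],
    pois: Mapping[str, PoiRecord] | Sequence[PoiRecord],
    graph: StreetGraph,
) -> dict[int, tuple[int, int]]:
    """Per-edge (outlet_count, school_count); also writes the counts onto the
    graph's edges.  Counts sum to the number of snapped POIs per category."""
    if not isinstance(pois, Mapping):
        pois = {p.id: p for p in pois}
    counts = {eid: [0, 0] for eid in graph.edges}
    for snap in snaps:
        cat = pois[snap.poi_id].category
        if cat == "outlet":
            counts[snap.edge_id][0] += 1
        elif cat == "school":
            counts[snap.edge_id][1] += 1
    for eid, (n_out, n_sch) in counts.items():
        graph.edges[eid].outlet_count = n_out
        graph.edges[eid].school_count = n_sch
    return {eid: (c[0], c[1]) for eid, c in counts.items()}
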