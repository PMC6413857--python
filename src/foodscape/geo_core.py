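"""Planar geometry primitives and geometry/attribute file I/O.

All coordinates are planar easting/northing in meters (British-National-Grid
style). There is no geographic (lat/lon) support and no projection handling:
every operation assumes a flat plane, which is what national mapping agencies
deliver for street geometry.

Geometry predicates and clipping delegate to :mod:`shapely`; the thin domain
types here carry the identifiers and invariants the rest of the pipeline
relies on (stable ids, no zero-length polylines, closed rings).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import shapely
from shapely.geometry import LineString, Point as _ShapelyPoint, Polygon as _ShapelyPolygon
from shapely.geometry import mapping as _shapely_mapping

#: classification tolerance for "on boundary", in meters.  Far below any road
#: length scale, far above double rounding error.
BOUNDARY_TOL = 1e-6

#: relative tolerance for length-conservation checks after clipping/splitting.
LENGTH_RTOL = 1e-9


class GeometryError(ValueError):
    """Invalid or degenerate geometry."""


class FileFormatError(ValueError):
    """Malformed GeoJSON or CSV input."""


class Point(NamedTuple):
    """Planar point; ``x`` easting, ``y`` northing, both in meters."""

    x: float
    y: float


def _check_finite(p: Point) -> None:
    if not (math.isfinite(p[0]) and math.isfinite(p[1])):
        raise GeometryError(f"non-finite coordinates: {p!r}")


@dataclass
class Polyline:
    """Ordered chain of >= 2 points with a stable identifier.

    Consecutive duplicate points are disallowed and the total length must be
    strictly positive.
    """

    points: list[Point]
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise GeometryError(f"polyline {self.id!r} needs >=2 points")
        pts = [Point(float(p[0]), float(p[1])) for p in self.points]
        for p in pts:
            _check_finite(p)
        for a, b in zip(pts, pts[1:]):
            if a == b:
                raise GeometryError(f"polyline {self.id!r} has consecutive duplicate point {a}")
        self.points = pts
        if self.length() <= 0.0:
            raise GeometryError(f"polyline {self.id!r} has zero length")

    def length(self) -> float:
        return sum(euclidean_distance(a, b) for a, b in zip(self.points, self.points[1:]))

    def to_shapely(self) -> LineString:
        return LineString(self.points)


@dataclass
class Polygon:
    """Simple polygon with optional holes.

    The exterior ring is stored closed (first vertex repeated last) and the
    polygon is validated as non-self-intersecting on construction.
    """

    exterior: list[Point]
    holes: list[list[Point]] = field(default_factory=list)
    id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        ext = [Point(float(p[0]), float(p[1])) for p in self.exterior]
        if len(ext) < 4:
            raise GeometryError(f"polygon {self.id!r}: exterior ring needs >=4 vertices (closed)")
        if ext[0] != ext[-1]:
            raise GeometryError(f"polygon {self.id!r}: exterior ring not closed")
        for p in ext:
            _check_finite(p)
        self.exterior = ext
        self.holes = [[Point(float(p[0]), float(p[1])) for p in ring] for ring in self.holes]
        for ring in self.holes:
            if ring and ring[0] != ring[-1]:
                raise GeometryError(f"polygon {self.id!r}: hole ring not closed")
        shp = _ShapelyPolygon(self.exterior, self.holes)
        if not shp.is_valid:
            raise GeometryError(f"polygon {self.id!r} is invalid: {shapely.is_valid_reason(shp)}")
        self._shapely = shp

    def to_shapely(self) -> _ShapelyPolygon:
        return self._shapely


@dataclass
class ClipPiece:
    """One piece of a polyline clipped against a polygon.

    ``relation`` is ``"inside"`` for pieces in the polygon interior and
    ``"boundary"`` for runs coincident with the polygon boundary.
    """

    geometry: Polyline
    relation: str
    parent_id: str

    def __post_init__(self) -> None:
        if self.relation not in ("inside", "boundary"):
            raise ValueError(f"bad relation {self.relation!r}")


# ---------------------------------------------------------------------------
# scalar geometry


def euclidean_distance(p: Point | tuple, q: Point | tuple) -> float:
    """Straight-line ("as the crow flies") distance in meters."""
    _check_finite(Point(*p))
    _check_finite(Point(*q))
    return math.hypot(p[0] - q[0], p[1] - q[1])


def point_to_segment(p: Point | tuple, a: Point | tuple, b: Point | tuple) -> tuple[float, float]:
    """Distance from ``p`` to segment ``a-b`` and the foot-point parameter.

    Returns ``(distance, t)`` where ``t`` in [0, 1] locates the closest point
    ``a + t*(b-a)``.  Degenerate segments (``a == b``) are rejected.
    """
    _check_finite(Point(*p))
    ax, ay, bx, by = a[0], a[1], b[0], b[1]
    dx, dy = bx - ax, by - ay
    seg2 = dx * dx + dy * dy
    if seg2 == 0.0:
        raise GeometryError(f"degenerate segment {a!r} == {b!r}")
    t = ((p[0] - ax) * dx + (p[1] - ay) * dy) / seg2
    t = min(1.0, max(0.0, t))
    return math.hypot(p[0] - (ax + t * dx), p[1] - (ay + t * dy)), t


def polyline_length(line: Polyline) -> float:
    """Total length: sum of consecutive-vertex Euclidean distances."""
    return line.length()


def point_in_polygon(p: Point | tuple, poly: Polygon, tol: float = BOUNDARY_TOL) -> str:
    """Classify ``p`` as ``"inside"``, ``"outside"`` or ``"on_boundary"``.

    Boundary membership is detected within ``tol`` meters.
    """
    _check_finite(Point(*p))
    shp = poly.to_shapely()
    pt = _ShapelyPoint(p[0], p[1])
    if shp.boundary.distance(pt) <= tol:
        return "on_boundary"
    return "inside" if shp.contains(pt) else "outside"


# ---------------------------------------------------------------------------
# clipping


def _iter_lines(geom) -> Iterable[LineString]:
    """Yield the 1-D components of a shapely geometry, dropping points."""
    if geom.is_empty:
        return
    gt = geom.geom_type
    if gt == "LineString":
        yield geom
    elif gt in ("MultiLineString", "GeometryCollection"):
        for g in geom.geoms:
            yield from _iter_lines(g)
    # Point / MultiPoint touch artefacts carry no length: ignored.


def _line_to_polyline(ls: LineString, pid: str) -> Polyline:
    pts: list[Point] = []
    for x, y in ls.coords:
        q = Point(x, y)
        if not pts or pts[-1] != q:
            pts.append(q)
    return Polyline(pts, id=pid)


def clip_polyline(line: Polyline, poly: Polygon, tol: float = BOUNDARY_TOL) -> list[ClipPiece]:
    """Clip ``line`` against ``poly``.

    Returns the pieces of ``line`` lying inside the polygon plus runs
    coincident with its boundary (flagged ``"boundary"``).  Cut points are the
    exact line/edge intersections computed by shapely.  The empty list means
    the polyline is entirely outside.
    """
    shp_line = line.to_shapely()
    shp_poly = poly.to_shapely()
    pieces: list[ClipPiece] = []

    boundary_part = shp_line.intersection(shp_poly.boundary)
    n_bound = 0
    for ls in _iter_lines(boundary_part):
        if ls.length <= tol:
            continue
        pieces.append(
            ClipPiece(_line_to_polyline(ls, f"{line.id}|b{n_bound}"), "boundary", line.id)
        )
        n_bound += 1

    inside_part = shp_line.intersection(shp_poly)
    if n_bound:
        inside_part = inside_part.difference(boundary_part)
    n_in = 0
    for ls in _iter_lines(inside_part):
        if ls.length <= tol:
            continue
        pieces.append(ClipPiece(_line_to_polyline(ls, f"{line.id}|i{n_in}"), "inside", line.id))
        n_in += 1
    return pieces


# ---------------------------------------------------------------------------
# I/O: GeoJSON feature collections and CSV attribute tables


@dataclass
class Feature:
    """One GeoJSON feature: a domain geometry plus a properties dict."""

    geometry: Point | Polyline | Polygon
    properties: dict


def _geometry_to_geojson(geom) -> dict:
    if isinstance(geom, Point):
        return {"type": "Point", "coordinates": [geom.x, geom.y]}
    if isinstance(geom, Polyline):
        return _shapely_mapping(geom.to_shapely())
    if isinstance(geom, Polygon):
        return _shapely_mapping(geom.to_shapely())
    raise FileFormatError(f"unsupported geometry type {type(geom).__name__}")


def _geometry_from_geojson(gj: dict, fid: str, name: str) -> Point | Polyline | Polygon:
    gtype = gj.get("type")
    if gtype == "Point":
        x, y = gj["coordinates"]
        p = Point(float(x), float(y))
        _check_finite(p)
        return p
    if gtype == "LineString":
        return Polyline([Point(float(x), float(y)) for x, y in gj["coordinates"]], id=fid)
    if gtype == "Polygon":
        rings = gj["coordinates"]
        if not rings:
            raise GeometryError(f"feature {fid!r}: polygon without rings")
        ext = [Point(float(x), float(y)) for x, y in rings[0]]
        if not ext or ext[0] != ext[-1]:
            raise GeometryError(f"feature {fid!r}: unclosed exterior ring")
        holes = [[Point(float(x), float(y)) for x, y in r] for r in rings[1:]]
        return Polygon(ext, holes, id=fid, name=name)
    raise FileFormatError(f"feature {fid!r}: unsupported geometry type {gtype!r}")


def write_geojson(features: Sequence[Feature], path) -> None:
    """Write features as an RFC 7946-shaped FeatureCollection.

    Coordinates are planar meters, declared through a ``crs_note`` property so
    no consumer mistakes them for degrees; values are written with ``repr``
    precision so round-trips are lossless.
    """
    fc = {
        "type": "FeatureCollection",
        "crs_note": "planar easting/northing in meters (not geographic)",
        "features": [
            {
                "type": "Feature",
                "geometry": _geometry_to_geojson(f.geometry),
                "properties": f.properties,
            }
            for f in features
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(fc, fh)


def read_geojson(path) -> list[Feature]:
    """Read a FeatureCollection written by :func:`write_geojson` (or any
    planar GeoJSON limited to Point/LineString/Polygon)."""
    with open(path, encoding="utf-8") as fh:
        try:
            fc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FileFormatError(f"{path}: malformed JSON at line {exc.lineno}") from exc
    if fc.get("type") != "FeatureCollection":
        raise FileFormatError(f"{path}: not a FeatureCollection")
    out: list[Feature] = []
    for i, feat in enumerate(fc.get("features", [])):
        props = feat.get("properties") or {}
        fid = str(props.get("id", i))
        name = str(props.get("name", ""))
        geom = feat.get("geometry")
        if geom is None:
            raise FileFormatError(f"{path}: feature {i} has no geometry")
        try:
            out.append(Feature(_geometry_from_geojson(geom, fid, name), props))
        except (KeyError, TypeError) as exc:
            raise FileFormatError(f"{path}: feature {i} malformed: {exc}") from exc
    return out


def read_table(path, required: Sequence[str] = ()) -> list[dict]:
    """Read a UTF-8 CSV with a header row into a list of dicts."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FileFormatError(f"{path}: empty CSV")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise FileFormatError(f"{path}: missing required column(s) {missing}")
        return list(reader)


def write_table(rows: Sequence[dict], path, columns: Sequence[str] | None = None) -> None:
    """Write dict rows to CSV with a header; column order is stable."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns))
        writer.writeheader()
        for row in rows:
            writer.writerow(row)
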