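"""Synthetic districts, small areas, road grids, POIs and deprivation scores.

Every downstream stage of the pipeline is exercised on worlds produced here,
standing in for the proprietary national datasets (boundary polygons, open
roads, commercial POI records, deprivation indices).  The generator emulates
the structural features the analysis depends on:

* roads stored as short segment chains that bend and intersect (a perturbed
  square grid, one polyline per inter-node link, optional mid-segment bends);
* roads crossing administrative boundaries (each grid row crosses every
  interior district border, so clipping/duplication paths are exercised);
* strongly clustered fast-food outlets (a sequential paired-placement
  process: a configured fraction of outlets is dropped within network reach
  ``outlet_pair_radius_m`` of another outlet) versus weakly clustered schools
  (homogeneous on edges with a minimum dispersion);
* a continuous deprivation score per small area (linear gradient plus noise);
* occasional incomplete POI records (blank district code or postal code);
* the three disconnection pathologies: a detached hamlet, a critical
  connector road lying administratively in the neighbouring district, and an
  island group (kept free of POIs so dropping the district is clean).

Districts are unit squares of side ``district_size_m`` arranged in a row;
grid nodes sit half a pitch away from every border so only the deliberate
cross-border roads cross districts.  All randomness flows from one seeded
:class:`numpy.random.Generator`, so a seed fully determines a world.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString

from .geo_core import Point, Polygon, Polyline, Feature, write_geojson, write_table
from .poi_assignment import PoiRecord
from .deprivation_overlay import AreaUnit

PATHOLOGIES = ("hamlet", "boundary_connector", "islands")


class ConfigError(ValueError):
    """Infeasible or inconsistent synthetic-world configuration."""


@dataclass
class SyntheticConfig:
    """Generative parameters of a synthetic world.

    Defaults are the conditions the analysis is studied under: five
    district squares of 18 km side with a 400 m road pitch (about 2000
    nodes per district, mean degree 2-3), 2000 outlets of which 80% are
    placed as close pairs within 120 m network reach, 300 weakly clustered
    schools, 1% incomplete POI records, and a west-east deprivation
    gradient over 3x3 small areas per district.
    """

    seed: int = 0
    n_districts: int = 5
    district_size_m: float = 18000.0
    road_grid_pitch_m: float = 400.0
    road_jitter_frac: float = 0.15
    road_bend_fraction: float = 0.3
    spur_fraction: float = 0.10
    n_outlets: int = 2000
    n_schools: int = 300
    outlet_pair_fraction: float = 0.8
    outlet_pair_radius_m: float = 120.0
    outlet_same_spot_fraction: float = 0.15
    school_dispersion_m: float = 800.0
    missing_record_fraction: float = 0.01
    city_code_fraction: float = 0.05
    pathology_flags: tuple[str, ...] = ()
    areas_per_side: int = 3
    imd_min: float = 5.0
    imd_max: float = 45.0
    imd_noise_sd: float = 2.0
    gradient_axis: str = "x"

    def validate(self) -> None:
        for name in (
            "road_jitter_frac", "road_bend_fraction", "spur_fraction",
            "outlet_pair_fraction", "outlet_same_spot_fraction",
            "missing_record_fraction", "city_code_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if min(self.n_districts, self.n_outlets, self.n_schools) < 0:
            raise ConfigError("counts must be >= 0")
        if self.n_districts == 0:
            raise ConfigError("need at least one district")
        if self.road_grid_pitch_m <= 0:
            raise ConfigError("pitch must be > 0")
        if self.road_grid_pitch_m >= self.district_size_m:
            raise ConfigError("pitch larger than district size")
        if abs(self.district_size_m / self.road_grid_pitch_m
               - round(self.district_size_m / self.road_grid_pitch_m)) > 1e-9:
            raise ConfigError("district_size_m must be a multiple of road_grid_pitch_m")
        if self.road_jitter_frac > 0.45:
            raise ConfigError("road_jitter_frac > 0.45 lets nodes jitter across borders")
        unknown = set(self.pathology_flags) - set(PATHOLOGIES)
        if unknown:
            raise ConfigError(f"unknown pathology flags {sorted(unknown)}")
        rows = int(round(self.district_size_m / self.road_grid_pitch_m))
        if "hamlet" in self.pathology_flags and rows < 6:
            raise ConfigError("hamlet pathology needs >= 6 grid rows")
        if "boundary_connector" in self.pathology_flags and (
            self.n_districts < 2 or rows < 4
        ):
            raise ConfigError("boundary_connector needs >= 2 districts and >= 4 rows")
        if "islands" in self.pathology_flags and rows < 9:
            raise ConfigError("islands pathology needs >= 9 grid rows")
        if ("islands" in self.pathology_flags
                and "boundary_connector" in self.pathology_flags
                and self.n_districts < 3):
            raise ConfigError("islands + boundary_connector need >= 3 districts")
        if self.gradient_axis not in ("x", "y"):
            raise ConfigError("gradient_axis must be 'x' or 'y'")


@dataclass
class SyntheticWorld:
    """A generated world plus the realized generative truth."""

    config: SyntheticConfig
    districts: list[Polygon]
    areas: list[AreaUnit]
    roads: list[Polyline]
    pois: list[PoiRecord]
    name_map: dict[str, str]
    truth: dict = field(default_factory=dict)


def _district_index(cfg: SyntheticConfig, x: float) -> int:
    return min(cfg.n_districts - 1, max(0, int(x // cfg.district_size_m)))


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate a deterministic synthetic world from ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    S = config.district_size_m
    p = config.road_grid_pitch_m
    rows = int(round(S / p))
    cols = rows * config.n_districts
    W = S * config.n_districts

    districts = [
        Polygon(
            [Point(i * S, 0.0), Point((i + 1) * S, 0.0), Point((i + 1) * S, S),
             Point(i * S, S), Point(i * S, 0.0)],
            id=f"D{i}",
            name=f"Town {i}",
        )
        for i in range(config.n_districts)
    ]

    # areas: aligned sub-squares per district, deprivation = gradient + noise
    areas: list[AreaUnit] = []
    a = config.areas_per_side
    aw = S / a
    for di in range(config.n_districts):
        for ai in range(a):
            for aj in range(a):
                x0, y0 = di * S + ai * aw, aj * aw
                cx, cy = x0 + aw / 2, y0 + aw / 2
                frac = (cx / W) if config.gradient_axis == "x" else (cy / S)
                score = (
                    config.imd_min
                    + (config.imd_max - config.imd_min) * frac
                    + rng.normal(0.0, config.imd_noise_sd)
                )
                areas.append(
                    AreaUnit(
                        id=f"A{di}.{ai}.{aj}",
                        geometry=Polygon(
                            [Point(x0, y0), Point(x0 + aw, y0), Point(x0 + aw, y0 + aw),
                             Point(x0, y0 + aw), Point(x0, y0)],
                            id=f"A{di}.{ai}.{aj}",
                        ),
                        imd_score=float(max(0.1, score)),
                    )
                )

    # jittered grid nodes; nodes sit p/2 from borders so jitter cannot cross
    gx = p / 2 + p * np.arange(cols)
    gy = p / 2 + p * np.arange(rows)
    jit = config.road_jitter_frac * p
    nx_ = rng.uniform(-jit, jit, size=(cols, rows))
    ny_ = rng.uniform(-jit, jit, size=(cols, rows))
    node_x = gx[:, None] + nx_
    node_y = gy[None, :] + ny_

    removed_links: set[tuple] = set()  # ("h", c, r) or ("v", c, r): link removed
    extra_roads: list[tuple[list[Point], int | None]] = []  # (points, home district)
    pathology_districts: dict[str, str] = {}
    excluded_districts: set[int] = set()

    if "hamlet" in config.pathology_flags:
        dh = 0
        pathology_districts["hamlet"] = f"D{dh}"
        # detach the 3x3 corner block: remove every link incident to the ring
        # (col 3 / row 3), so the gap to the main grid is two pitches wide
        for r in range(0, 4):
            removed_links |= {("h", 2, r), ("h", 3, r), ("v", 3, r if r < 3 else r)}
        for c in range(0, 4):
            removed_links |= {("v", c, 2), ("v", c, 3), ("h", c, 3)}

    if "boundary_connector" in config.pathology_flags:
        db = 1
        pathology_districts["boundary_connector"] = f"D{db}"
        mid = rows // 2
        c0 = db * rows
        for c in range(c0, c0 + rows):
            removed_links.add(("v", c, mid - 1))
        ax, ay = node_x[c0, mid - 1], node_y[c0, mid - 1]
        bx, by = node_x[c0, mid], node_y[c0, mid]
        xw = db * S - 0.75 * p  # inside the western neighbour
        extra_roads.append(
            ([Point(ax, ay), Point(xw, ay), Point(xw, by), Point(bx, by)], None)
        )

    if "islands" in config.pathology_flags:
        di = config.n_districts - 1
        pathology_districts["islands"] = f"D{di}"
        excluded_districts.add(di)
        third = rows // 3
        band_rows = {third, third + 1, 2 * third + 1, 2 * third + 2}
        c0 = di * rows
        for c in range(c0, c0 + rows):
            for r in range(rows):
                if r in band_rows:
                    removed_links |= {
                        ("h", c - 1, r), ("h", c, r), ("v", c, r - 1), ("v", c, r),
                    }

    # emit road polylines per surviving grid link; a bent link becomes a
    # chain of separate 2-point segments (a new segment at every bend, with
    # the bend vertex turning into a degree-2 node, as road data encodes it)
    roads: list[Polyline] = []
    road_home: list[int | None] = []  # district index when fully inside one

    def add_road(points: list[Point], home: int | None) -> None:
        roads.append(Polyline(points, id=f"r{len(roads)}"))
        road_home.append(home)

    def emit_link(a_pt: Point, b_pt: Point, home: int | None) -> None:
        if rng.random() >= config.road_bend_fraction:
            add_road([a_pt, b_pt], home)
            return
        dx, dy = b_pt.x - a_pt.x, b_pt.y - a_pt.y
        norm = float(np.hypot(dx, dy))
        nx2, ny2 = -dy / norm, dx / norm
        chain = [a_pt]
        for frac in (1 / 3, 2 / 3):
            off = rng.uniform(-0.15, 0.15) * p
            chain.append(Point(a_pt.x + frac * dx + nx2 * off,
                               a_pt.y + frac * dy + ny2 * off))
        chain.append(b_pt)
        for s_pt, e_pt in zip(chain, chain[1:]):
            add_road([s_pt, e_pt], home)

    for c in range(cols):
        for r in range(rows):
            a_pt = Point(node_x[c, r], node_y[c, r])
            if c + 1 < cols and ("h", c, r) not in removed_links:
                b_pt = Point(node_x[c + 1, r], node_y[c + 1, r])
                da, db_ = _district_index(config, a_pt.x), _district_index(config, b_pt.x)
                emit_link(a_pt, b_pt, da if da == db_ else None)
            if r + 1 < rows and ("v", c, r) not in removed_links:
                b_pt = Point(node_x[c, r + 1], node_y[c, r + 1])
                emit_link(a_pt, b_pt, _district_index(config, a_pt.x))
            if rng.random() < config.spur_fraction:
                ang = rng.uniform(0, 2 * np.pi)
                ln = rng.uniform(0.25, 0.45) * p
                e_pt = Point(a_pt.x + ln * np.cos(ang), a_pt.y + ln * np.sin(ang))
                if 0 < e_pt.x < W and 0 < e_pt.y < S and (
                    _district_index(config, e_pt.x) == _district_index(config, a_pt.x)
                ):
                    add_road([a_pt, e_pt], _district_index(config, a_pt.x))
    for pts, home in extra_roads:
        add_road(pts, home)

    # eligible roads for POI placement: fully inside a non-excluded district
    eligible = [
        i for i, home in enumerate(road_home)
        if home is not None and home not in excluded_districts
    ]
    if not eligible and (config.n_outlets > 0 or config.n_schools > 0):
        raise ConfigError("no roads fully inside a district to place POIs on")
    elig_lines = [LineString(roads[i].points) for i in eligible]
    elig_len = np.array([ln.length for ln in elig_lines])
    elig_prob = elig_len / elig_len.sum() if len(eligible) else None

    def uniform_on_network() -> tuple[int, float]:
        """Length-weighted road index (into ``eligible``) and arc offset."""
        ri = int(rng.choice(len(eligible), p=elig_prob))
        return ri, float(rng.uniform(0.0, elig_len[ri]))

    def coords(ri: int, off: float) -> Point:
        pt = elig_lines[ri].interpolate(off)
        return Point(pt.x, pt.y)

    # --- outlets: sequential paired placement -------------------------------
    pois: list[PoiRecord] = []
    outlet_pos: list[tuple[int, float]] = []
    clustered = (
        rng.random(config.n_outlets) < config.outlet_pair_fraction
        if config.n_outlets else np.zeros(0, dtype=bool)
    )
    truly_clustered = clustered.copy()
    r_eff = 0.95 * config.outlet_pair_radius_m
    pending: int | None = None
    pair_anchor: list[int] = []  # indices of outlets usable as odd-leftover anchors
    for i in range(config.n_outlets):
        if not clustered[i] or not eligible:
            outlet_pos.append(uniform_on_network())
            if not eligible:
                truly_clustered[i] = False
            continue
        if pending is None:
            outlet_pos.append(uniform_on_network())
            pending = i
        else:
            ri, off = outlet_pos[pending]
            if rng.random() < config.outlet_same_spot_fraction:
                new_off = off
            else:
                lo, hi = max(0.0, off - r_eff), min(elig_len[ri], off + r_eff)
                new_off = float(rng.uniform(lo, hi))
            outlet_pos.append((ri, new_off))
            pair_anchor.extend((pending, i))
            pending = None
    if pending is not None:
        if pair_anchor:
            anchor = int(rng.choice(pair_anchor))
            ri, off = outlet_pos[anchor]
            lo, hi = max(0.0, off - r_eff), min(elig_len[ri], off + r_eff)
            outlet_pos[pending] = (ri, float(rng.uniform(lo, hi)))
        else:
            truly_clustered[pending] = False

    for i, (ri, off) in enumerate(outlet_pos):
        loc = coords(ri, off)
        pois.append(PoiRecord(
            id=f"o{i}", category="outlet", location=loc,
            postal_code=f"SY{i % 90:02d} {i % 9}AA",
            district_code=f"Town {_district_index(config, loc.x)}",
        ))

    # --- schools: homogeneous with minimum dispersion ------------------------
    school_xy: list[Point] = []
    for i in range(config.n_schools):
        if not eligible:
            break
        loc = None
        for _ in range(30):
            ri, off = uniform_on_network()
            cand = coords(ri, off)
            if all(
                (cand.x - s.x) ** 2 + (cand.y - s.y) ** 2
                >= config.school_dispersion_m ** 2
                for s in school_xy
            ):
                loc = cand
                break
        if loc is None:
            loc = cand  # dispersion unattainable: accept last draw
        school_xy.append(loc)
        pois.append(PoiRecord(
            id=f"s{i}", category="school", location=loc,
            postal_code=f"SY{i % 90:02d} {i % 9}SS",
            district_code=f"Town {_district_index(config, loc.x)}",
        ))

    # --- name map + record corruption ----------------------------------------
    name_map = {f"Town {i}": f"D{i}" for i in range(config.n_districts)}
    n_city = 0
    for rec in pois:
        if rng.random() < config.city_code_fraction:
            di = name_map[rec.district_code]
            code = f"Ward {n_city} of {di}"
            name_map[code] = di
            rec.district_code = code
            n_city += 1
    n_blanked = 0
    for rec in pois:
        if rng.random() < config.missing_record_fraction:
            if rng.random() < 0.5:
                rec.district_code = ""
            else:
                rec.postal_code = ""
            n_blanked += 1

    n_out = config.n_outlets
    truth = {
        "realized_pair_fraction": (
            float(np.mean(truly_clustered)) if n_out else float("nan")
        ),
        "n_clustered_outlets": int(truly_clustered.sum()),
        "pathologies": pathology_districts,
        "n_blanked_records": n_blanked,
        "n_city_coded_records": n_city,
        "area_imd": {u.id: u.imd_score for u in areas},
        "outlet_clustered": {
            f"o{i}": bool(truly_clustered[i]) for i in range(n_out)
        },
        "total_road_length_m": float(sum(r.length() for r in roads)),
    }
    return SyntheticWorld(
        config=config, districts=districts, areas=areas, roads=roads,
        pois=pois, name_map=name_map, truth=truth,
    )


def truth_report(world: SyntheticWorld) -> dict:
    """Realized generative parameters, for use as a test oracle."""
    t = world.truth
    return {
        "pathologies": sorted(t["pathologies"]),
        "pathology_districts": dict(t["pathologies"]),
        "realized_pair_fraction": t["realized_pair_fraction"],
        "n_outlets": sum(1 for p in world.pois if p.category == "outlet"),
        "n_schools": sum(1 for p in world.pois if p.category == "school"),
        "n_blanked_records": t["n_blanked_records"],
        "area_imd": dict(t["area_imd"]),
        "outlet_truth": dict(t["outlet_clustered"]),
    }


def write_world(world: SyntheticWorld, outdir) -> None:
    """Emit the GeoJSON/CSV files the pipeline consumes."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_geojson(
        [Feature(d, {"id": d.id, "name": d.name}) for d in world.districts],
        os.path.join(outdir, "districts.geojson"),
    )
    write_geojson(
        [Feature(u.geometry, {"id": u.id}) for u in world.areas],
        os.path.join(outdir, "areas.geojson"),
    )
    write_geojson(
        [Feature(r, {"id": r.id}) for r in world.roads],
        os.path.join(outdir, "roads.geojson"),
    )
    write_table(
        [
            {"area_id": u.id, "imd_score": repr(u.imd_score)}
            for u in world.areas
        ],
        os.path.join(outdir, "imd.csv"),
    )
    write_table(
        [
            {
                "id": p.id, "category": p.category,
                "x": repr(p.location.x), "y": repr(p.location.y),
                "postal_code": p.postal_code, "district_code": p.district_code,
            }
            for p in world.pois
        ],
        os.path.join(outdir, "pois.csv"),
    )
    write_table(
        [{"district_code": k, "district_id": v} for k, v in sorted(world.name_map.items())],
        os.path.join(outdir, "name_map.csv"),
    )
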