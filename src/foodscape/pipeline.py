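"""End-to-end orchestration: data stages, analyses, and a report bundle.

``run`` executes the five data stages (districts, roads, POIs, areas,
deprivation) followed by the three analyses (network/Euclidean distance
distributions with buffer curves, centrality-outlet correlations, and
deprivation-stratified scaling fits), writing a reproducible bundle of CSV/
JSON outputs.  Districts are processed independently; a failure in one is
logged and skipped without aborting the run.  The manifest records the
config hash and seed, and contains no timestamps, so identical runs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geo_core import Point, Polygon, Polyline, read_geojson, read_table
from .network_builder import (
    assign_roads_to_districts,
    build_graph,
    diagnose_connectivity,
    resolve_disconnection,
)
from .poi_assignment import (
    PoiRecord,
    count_per_edge,
    filter_pois,
    resolve_district,
    snap_all,
)
from .deprivation_overlay import (
    AreaUnit,
    assign_areas_to_edges,
    assign_imd,
    compute_tertiles,
    label_edges,
)
from .network_distances import (
    DEFAULT_BIN_EDGES,
    buffer_curve,
    euclidean_nearest,
    insert_snap_nodes,
    nearest_other_outlet_distances,
    nearest_school_distances,
)
from .centrality_analysis import (
    ApproximationConfig,
    UndefinedCorrelationError,
    approx_centrality,
    assign_outlets_to_nodes,
    correlate,
    prune_leaves,
    rank_nodes,
)
from .scaling_fit import fit_all
from .synthetic_geodata import SyntheticConfig, SyntheticWorld, generate_world

logger = logging.getLogger(__name__)

DEFAULT_STRATEGIES = {
    "boundary_connector": "reassign_connector",
    "hamlet": "split_district",
    "islands": "drop_district",
}


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Inputs and knobs for one full run.

    Exactly one of ``synthetic`` (generator settings) or ``input_dir``
    (directory of GeoJSON/CSV files) must be given.
    """

    out_dir: str
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    approx: ApproximationConfig = field(default_factory=ApproximationConfig)
    strategies: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_STRATEGIES))
    prune_iterative: bool = False
    max_resolution_rounds: int = 3

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw.pop("synthetic"))
            if "pathology_flags" in syn:
                syn["pathology_flags"] = tuple(syn["pathology_flags"])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        if "approx" in raw and raw["approx"] is not None:
            kwargs["approx"] = ApproximationConfig(**raw.pop("approx"))
        if "bin_edges" in raw and raw["bin_edges"] is not None:
            kwargs["bin_edges"] = tuple(float(x) for x in raw.pop("bin_edges"))
        for key in ("out_dir", "input_dir", "strategies", "prune_iterative",
                    "max_resolution_rounds"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        return cls(**kwargs)

    def validate(self) -> None:
        if (self.synthetic is None) == (self.input_dir is None):
            raise PipelineConfigError(
                "exactly one of synthetic config or input_dir must be set"
            )

    def canonical_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        def enc(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class WorldData:
    """The five raw inputs, however obtained."""

    districts: list[Polygon]
    areas: list[AreaUnit]
    roads: list[Polyline]
    pois: list[PoiRecord]
    name_map: dict[str, str]


@dataclass
class ReportBundle:
    """All outputs of one run (also written as CSV/JSON under ``out_dir``)."""

    out_dir: str
    manifest: dict
    graph_stats: pd.DataFrame
    distances: pd.DataFrame
    buffer_curves: pd.DataFrame
    centrality: pd.DataFrame
    correlations: pd.DataFrame
    fits: pd.DataFrame
    diagnosis: list[dict]


def load_world(input_dir: str) -> WorldData:
    """Read districts/areas/roads/POIs from the on-disk GeoJSON/CSV layout."""
    def p(name):
        path = os.path.join(input_dir, name)
        if not os.path.exists(path):
            raise PipelineConfigError(f"missing input file {path}")
        return path

    districts = []
    for f in read_geojson(p("districts.geojson")):
        if not isinstance(f.geometry, Polygon):
            raise PipelineConfigError("districts.geojson must contain polygons")
        districts.append(f.geometry)
    scores = {
        r["area_id"]: float(r["imd_score"])
        for r in read_table(p("imd.csv"), required=("area_id", "imd_score"))
    }
    areas = []
    for f in read_geojson(p("areas.geojson")):
        aid = f.geometry.id
        if aid not in scores:
            raise PipelineConfigError(f"area {aid} missing from imd.csv")
        areas.append(AreaUnit(id=aid, geometry=f.geometry, imd_score=scores[aid]))
    roads = [f.geometry for f in read_geojson(p("roads.geojson"))]
    pois = [
        PoiRecord(
            id=r["id"], category=r["category"],
            location=Point(float(r["x"]), float(r["y"])),
            postal_code=r.get("postal_code", ""),
            district_code=r.get("district_code", ""),
        )
        for r in read_table(p("pois.csv"), required=("id", "category", "x", "y"))
    ]
    name_map = {
        r["district_code"]: r["district_id"]
        for r in read_table(p("name_map.csv"), required=("district_code", "district_id"))
    }
    return WorldData(districts=districts, areas=areas, roads=roads,
                     pois=pois, name_map=name_map)


def _resolve_all(districts, segments, poi_edges_by_district, strategies, rounds):
    """Diagnose every district; apply the configured strategy per archetype.

    Boundary connectors are resolved first: re-assigning the bridging
    segment removes the stray fragment from the neighbouring district before
    that neighbour is considered for splitting.
    """
    log: list[dict] = []
    priority = {"boundary_connector": 0, "hamlet": 1, "islands": 2}
    seen: set[tuple] = set()
    for _ in range(rounds * max(len(districts), 1)):
        diagnoses = []
        for dist in districts:
            g = build_graph(segments, dist.id)
            if g.m == 0:
                continue
            diag = diagnose_connectivity(g, poi_edges_by_district.get(dist.id))
            if diag.archetype != "none":
                diagnoses.append(diag)
        diagnoses = [d for d in diagnoses
                     if (d.district_id, d.archetype) not in seen]
        if not diagnoses:
            break
        diag = min(diagnoses, key=lambda d: (priority.get(d.archetype, 9), d.district_id))
        strategy = strategies.get(diag.archetype)
        entry = {
            "district": diag.district_id, "archetype": diag.archetype,
            "n_components": len(diag.components),
            "unreachable_pois": diag.unreachable_pois,
            "strategy": strategy,
        }
        if strategy is None:
            entry["status"] = "unresolved"
            seen.add((diag.district_id, diag.archetype))
            log.append(entry)
            continue
        try:
            districts, segments = resolve_disconnection(
                districts, segments, diag, strategy
            )
            entry["status"] = "applied"
        except Exception as exc:  # strategy failed: log, do not retry forever
            entry["status"] = f"failed: {exc}"
            seen.add((diag.district_id, diag.archetype))
        log.append(entry)
    return districts, segments, log


def run(config: PipelineConfig) -> ReportBundle:
    """Execute the full pipeline and write the report bundle."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    if config.synthetic is not None:
        synth: SyntheticWorld = generate_world(config.synthetic)
        world = WorldData(districts=synth.districts, areas=synth.areas,
                          roads=synth.roads, pois=synth.pois,
                          name_map=synth.name_map)
        seed = config.synthetic.seed
    else:
        world = load_world(config.input_dir)
        seed = config.approx.seed
    if not world.roads or not world.districts:
        raise PipelineConfigError("empty world: no roads or no districts")

    logger.info("stage 1-2: assigning %d roads to %d districts",
                len(world.roads), len(world.districts))
    segments = assign_roads_to_districts(world.roads, world.districts)

    logger.info("stage 3: filtering %d POI records", len(world.pois))
    kept, discard_tally = filter_pois(world.pois)
    by_district: dict[str, list[PoiRecord]] = {}
    n_unresolved = 0
    for rec in kept:
        did = resolve_district(rec, world.districts, world.name_map)
        if did is None:
            n_unresolved += 1
            continue
        by_district.setdefault(did, []).append(rec)

    # provisional snap (for unreachable-POI diagnosis), then resolve pathologies
    poi_edges_by_district: dict[str, dict[str, int]] = {}
    for did, recs in by_district.items():
        g = build_graph(segments, did)
        if g.m == 0:
            continue
        poi_edges_by_district[did] = {s.poi_id: s.edge_id for s in snap_all(recs, g)}
    districts, segments, diagnosis_log = _resolve_all(
        list(world.districts), segments, poi_edges_by_district,
        config.strategies, config.max_resolution_rounds,
    )
    # re-home POIs of split/dropped districts
    live_ids = {d.id for d in districts}
    for did in list(by_district):
        if did in live_ids:
            continue
        recs = by_district.pop(did)
        parts = [d.id for d in districts if d.id.startswith(f"{did}/part")]
        if not parts:
            logger.warning("district %s dropped: %d POIs discarded", did, len(recs))
            continue
        part_graphs = {pid: build_graph(segments, pid) for pid in parts}
        for rec in recs:
            best = None
            for pid, pg in part_graphs.items():
                if pg.m == 0:
                    continue
                snap = snap_all([rec], pg)[0]
                if best is None or snap.snap_distance < best[1].snap_distance:
                    best = (pid, snap)
            if best is not None:
                by_district.setdefault(best[0], []).append(rec)

    tertiles = compute_tertiles([a.imd_score for a in world.areas])

    graph_stats_rows, distance_rows, curve_specs = [], [], {}
    centrality_rows, correlation_rows = [], []
    school_net_by_tertile: dict[str, list[float]] = {}
    rng = np.random.default_rng(seed)

    for dist in sorted(districts, key=lambda d: d.id):
        try:
            result = _process_district(
                dist, segments, by_district.get(dist.id, []), world.areas,
                tertiles, config, rng,
            )
        except Exception:
            logger.exception("district %s failed: skipped", dist.id)
            continue
        if result is None:
            continue
        graph_stats_rows.append(result["stats"])
        distance_rows.extend(result["distances"])
        centrality_rows.extend(result["centrality"])
        correlation_rows.extend(result["correlations"])
        for rec in result["distances"]:
            if np.isfinite(rec["nearest_school_net_m"]):
                school_net_by_tertile.setdefault(str(rec["tertile"]), []).append(
                    rec["nearest_school_net_m"]
                )

    distances = pd.DataFrame(distance_rows)
    curves = _build_curves(distances, config.bin_edges)
    fits = fit_all(school_net_by_tertile, config.bin_edges) if school_net_by_tertile \
        else pd.DataFrame()

    manifest = {
        "config_hash": config.canonical_hash(),
        "seed": int(seed),
        "version": __version__,
        "n_districts": len(districts),
        "n_segments": len(segments),
        "n_unique_parent_roads": len({s.parent_road_id for s in segments}),
        "poi_discards": discard_tally,
        "n_unresolved_district_codes": n_unresolved,
        "tertile_boundaries": [tertiles.q1, tertiles.q2],
        "tertile_counts": list(tertiles.counts),
    }
    bundle = ReportBundle(
        out_dir=config.out_dir,
        manifest=manifest,
        graph_stats=pd.DataFrame(graph_stats_rows),
        distances=distances,
        buffer_curves=curves,
        centrality=pd.DataFrame(centrality_rows),
        correlations=pd.DataFrame(correlation_rows),
        fits=fits,
        diagnosis=diagnosis_log,
    )
    _write_bundle(bundle)
    return bundle


def _process_district(dist, segments, recs, areas, tertiles, config, rng):
    g = build_graph(segments, dist.id)
    if g.m == 0:
        logger.warning("district %s: empty graph, skipped", dist.id)
        return None
    snaps = snap_all(recs, g)

    # stages 4-5: area overlay, deprivation, tertile labels
    area_assignment = assign_areas_to_edges(g, areas, snaps)
    assign_imd(g, area_assignment, areas)
    label_edges(g, tertiles)
    count_per_edge(snaps, recs, g)

    total_len = sum(e.length for e in g.edges.values())
    stats_row = {
        "district": dist.id, "n_nodes": g.n, "n_edges": g.m,
        "total_length_m": total_len,
        "n_outlets": sum(1 for r in recs if r.category == "outlet"),
        "n_schools": sum(1 for r in recs if r.category == "school"),
    }

    # distances on the snapped network
    outlet_recs = {r.id: r for r in recs if r.category == "outlet"}
    school_recs = {r.id: r for r in recs if r.category == "school"}
    net = insert_snap_nodes(g, snaps)
    outlet_nodes = {pid: net.poi_nodes[pid] for pid in outlet_recs if pid in net.poi_nodes}
    school_nodes = {pid: net.poi_nodes[pid] for pid in school_recs if pid in net.poi_nodes}
    tertile_of_edge = {eid: e.tertile for eid, e in g.edges.items()}
    snap_by_poi = {s.poi_id: s for s in snaps}

    net_oo = (nearest_other_outlet_distances(net, outlet_nodes)
              if len(outlet_nodes) >= 2 else {})
    net_os = (nearest_school_distances(net, school_nodes, outlet_nodes)
              if school_nodes else {})
    o_ids = sorted(outlet_nodes)
    distance_rows = []
    if o_ids:
        o_xy = np.array([outlet_recs[p].location for p in o_ids], dtype=float)
        euc_oo = (euclidean_nearest(o_xy, o_xy, exclude_self=True)
                  if len(o_ids) >= 2 else np.full(len(o_ids), np.inf))
        s_xy = np.array([school_recs[p].location for p in sorted(school_nodes)],
                        dtype=float)
        euc_os = (euclidean_nearest(o_xy, s_xy) if len(s_xy) else
                  np.full(len(o_ids), np.inf))
        for i, pid in enumerate(o_ids):
            distance_rows.append({
                "district": dist.id, "poi_id": pid,
                "nearest_outlet_net_m": float(net_oo.get(pid, np.inf)),
                "nearest_school_net_m": float(net_os.get(pid, np.inf)),
                "nearest_outlet_euc_m": float(euc_oo[i]),
                "nearest_school_euc_m": float(euc_os[i]),
                "tertile": tertile_of_edge.get(snap_by_poi[pid].edge_id, 0),
            })

    # centrality + correlations on the leaf-pruned graph
    centrality_rows, correlation_rows = _district_centrality(
        g, o_ids, outlet_recs, dist.id, config, rng
    )
    return {
        "stats": stats_row, "distances": distance_rows,
        "centrality": centrality_rows, "correlations": correlation_rows,
    }


def _district_centrality(g, o_ids, outlet_recs, district_id, config, rng):
    pruned, removed = prune_leaves(g, iterative=config.prune_iterative)
    if pruned.n < 3:
        return [], []
    k = min(config.approx.k, pruned.n)
    cfg = ApproximationConfig(k=k, epsilon=config.approx.epsilon,
                              seed=int(rng.integers(2**31 - 1)))
    c_b = approx_centrality(pruned, cfg, "betweenness")
    c_c = approx_centrality(pruned, cfg, "closeness")
    rank_b = rank_nodes(c_b)
    rank_c = rank_nodes(c_c)
    o_xy = np.array([outlet_recs[p].location for p in o_ids], dtype=float).reshape(-1, 2)
    counts = assign_outlets_to_nodes(o_xy, pruned)
    order = pruned.node_order()
    xy = pruned.node_xy()
    centrality_rows = [
        {
            "district": district_id, "node": order[i],
            "x": xy[i, 0], "y": xy[i, 1],
            "c_B": c_b[i], "c_C": c_c[i],
            "rank_B": rank_b[i], "rank_C": rank_c[i],
            "outlet_count": int(counts[i]),
        }
        for i in range(pruned.n)
    ]
    correlation_rows = []
    for metric, ranks in (("betweenness", rank_b), ("closeness", rank_c)):
        for method in ("pearson", "spearman"):
            try:
                res = correlate(counts, ranks, method, district_id, metric)
            except UndefinedCorrelationError as exc:
                logger.warning("%s", exc)
                continue
            correlation_rows.append({
                "district": district_id, "metric": metric, "method": method,
                "r": res.r, "n_nodes": res.n_nodes,
            })
    return centrality_rows, correlation_rows


def _build_curves(distances: pd.DataFrame, bin_edges) -> pd.DataFrame:
    if distances.empty:
        return pd.DataFrame()
    specs = {
        ("outlet_outlet", "network"): "nearest_outlet_net_m",
        ("outlet_school", "network"): "nearest_school_net_m",
        ("outlet_outlet", "euclidean"): "nearest_outlet_euc_m",
        ("outlet_school", "euclidean"): "nearest_school_euc_m",
    }
    rows = []
    strata = [("overall", distances)] + [
        (str(t), sub) for t, sub in distances.groupby("tertile") if t in (1, 2, 3)
    ]
    for (pair, space), col in specs.items():
        for label, sub in strata:
            vals = sub[col][np.isfinite(sub[col])]
            if len(vals) == 0:
                continue
            curve = buffer_curve(vals, bin_edges)
            for edge, frac in zip(curve.bin_edges, curve.fraction_within):
                rows.append({
                    "pair": pair, "space": space, "stratum": label,
                    "bin_edge_m": edge, "fraction_within": frac,
                    "n_finite": curve.n_finite, "n_infinite": curve.n_infinite,
                })
    return pd.DataFrame(rows)


def _write_bundle(bundle: ReportBundle) -> None:
    out = bundle.out_dir
    for name, df in (
        ("graph_stats", bundle.graph_stats), ("distances", bundle.distances),
        ("buffer_curves", bundle.buffer_curves), ("centrality", bundle.centrality),
        ("correlations", bundle.correlations), ("fits", bundle.fits),
    ):
        df.to_csv(os.path.join(out, f"{name}.csv"), index=False)
    with open(os.path.join(out, "diagnosis.json"), "w", encoding="utf-8") as fh:
        json.dump(bundle.diagnosis, fh, indent=1, sort_keys=True)
    with open(os.path.join(out, "manifest.json"), "w", encoding="utf-8") as fh:
        json.dump(bundle.manifest, fh, indent=1, sort_keys=True)


def outlet_clustering_capture(world, radius: float = 120.0) -> dict:
    """Fraction of outlets with another outlet within ``radius`` network m.

    Runs only the stages the statistic needs (road assignment, snapping,
    snap-node insertion, early-stop nearest-outlet Dijkstra) on a world
    object, and evaluates the buffer curve at ``radius``.  Returns the
    capture fraction, the per-outlet distances and the outlet count.
    """
    segments = assign_roads_to_districts(world.roads, world.districts)
    kept, _ = filter_pois(world.pois)
    by_district: dict[str, list[PoiRecord]] = {}
    for rec in kept:
        if rec.category != "outlet":
            continue
        did = resolve_district(rec, world.districts, world.name_map)
        if did is not None:
            by_district.setdefault(did, []).append(rec)
    dists: list[float] = []
    ids: list[str] = []
    for did, recs in by_district.items():
        if len(recs) < 2:
            continue
        g = build_graph(segments, did)
        if g.m == 0:
            continue
        snaps = snap_all(recs, g)
        net = insert_snap_nodes(g, snaps)
        nodes = {r.id: net.poi_nodes[r.id] for r in recs}
        result = nearest_other_outlet_distances(net, nodes)
        for r in recs:
            ids.append(r.id)
            dists.append(result[r.id])
    arr = np.asarray(dists, dtype=float)
    finite = arr[np.isfinite(arr)]
    capture = float(np.mean(finite <= radius)) if finite.size else float("nan")
    return {"capture": capture, "distances": arr, "poi_ids": ids,
            "n_outlets": int(arr.size)}


def summarize(bundle: ReportBundle) -> dict:
    """Headline numbers of a bundle, traceable to its CSVs."""
    out: dict[str, Any] = {"manifest": bundle.manifest}
    curves = bundle.buffer_curves
    captures = {}
    if not curves.empty:
        for (pair, space), sub in curves.groupby(["pair", "space"]):
            overall = sub[sub.stratum == "overall"]
            for d in (120.0, 200.0, 400.0, 600.0):
                at = overall[overall.bin_edge_m <= d]
                if len(at):
                    captures[f"{pair}_{space}_at_{int(d)}m"] = float(
                        at.loc[at.bin_edge_m.idxmax(), "fraction_within"]
                    )
    out["capture_fractions"] = captures
    if bundle.correlations.empty:
        out["correlations"] = "unavailable"
    else:
        r = bundle.correlations["r"]
        out["correlations"] = {
            "n": int(len(r)),
            "share_within_pm_0.1": float(np.mean(np.abs(r) <= 0.1)),
            "mean_abs": float(np.abs(r).mean()),
            "max_abs": float(np.abs(r).max()),
        }
    if not bundle.fits.empty:
        loglog = bundle.fits[(bundle.fits.x_scale == "log")
                             & (bundle.fits.y_scale == "log")]
        out["loglog_exponents"] = {
            row.tertile: float(row.slope) for row in loglog.itertuples()
        }
        out["loglog_r_squared"] = {
            row.tertile: float(row.r_squared) for row in loglog.itertuples()
        }
    return out
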