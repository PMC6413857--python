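"""Betweenness/closeness centrality: pruned exact, pivot-approximated, ranked.

Betweenness of a node v sums, over all ordered pairs s != t != v, the
fraction of shortest s-t paths through v (Brandes dependency accumulation).
Closeness is the inverse of the sum of distances to all reachable nodes,
computed within each connected component; isolated nodes get 0.

Because street graphs are large, two cost reductions mirror common practice:

* degree-1 nodes are removed in a single pass before betweenness (no
  shortest path between two non-leaf nodes crosses a leaf, so their
  betweenness is 0 by construction; interior betweenness then excludes
  leaf-terminated paths, a deliberate and documented deviation from the
  textbook definition);
* the pivot (Eppstein-Wang style) approximation samples k source nodes
  without replacement and scales single-source quantities by n/k:
  betweenness ~ (n/k) * sum of pivot dependencies, inverse closeness
  ~ (n_C/k_C) * sum of distances from the component's pivots.  With k = n
  both estimators coincide with the exact values.

Centrality values are *indices*: only their order is meaningful, so scores
are converted to average-tie fractional ranks before correlating with
per-node outlet counts (Pearson and Spearman).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
from scipy.sparse.csgraph import dijkstra as _cs_dijkstra
from scipy import stats
from scipy.spatial import cKDTree

from .network_builder import StreetGraph
from . import _graphalg

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """A correlation input is constant: the coefficient is undefined."""


@dataclass
class ApproximationConfig:
    """Pivot-sampling parameters.

    ``k`` defaults to 109 pivots with a 5% error margin ``epsilon``, the
    operating point found adequate across district street networks.
    """

    k: int = 109
    epsilon: float = 0.05
    seed: int = 0

    def validate(self, n: int) -> None:
        if not 1 <= self.k <= n:
            raise ValueError(f"k={self.k} outside [1, n={n}]")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError(f"epsilon={self.epsilon} outside (0, 1)")


@dataclass
class CentralityScores:
    """Per-node centralities, fractional ranks and bookkeeping flags.

    Arrays are aligned with ``node_order`` (the graph's dense node order).
    """

    node_order: list[int]
    c_b: np.ndarray
    c_c: np.ndarray
    rank_b: np.ndarray
    rank_c: np.ndarray
    pruned_leaf: np.ndarray
    unreachable: np.ndarray


@dataclass
class CorrelationResult:
    district_id: str
    method: str  # pearson | spearman
    metric: str  # betweenness | closeness
    r: float
    n_nodes: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")


# ---------------------------------------------------------------------------
# graph reductions


def prune_leaves(graph: StreetGraph, iterative: bool = False) -> tuple[StreetGraph, list[int]]:
    """Remove degree-1 nodes (and their edges).

    Single pass by default: all current leaves are removed together, which
    does not consume chains the way iterative pruning would.  Removed nodes
    are reported with centrality 0 downstream.
    """
    g = StreetGraph(district_id=graph.district_id, nodes=dict(graph.nodes),
                    edges=dict(graph.edges))
    removed: list[int] = []
    while True:
        degree: dict[int, int] = {nid: 0 for nid in g.nodes}
        for e in g.edges.values():
            degree[e.u] += 1
            degree[e.v] += 1
        leaves = {nid for nid, d in degree.items() if d == 1}
        if not leaves:
            break
        removed.extend(sorted(leaves))
        g.edges = {eid: e for eid, e in g.edges.items()
                   if e.u not in leaves and e.v not in leaves}
        g.nodes = {nid: p for nid, p in g.nodes.items() if nid not in leaves}
        if not iterative:
            break
    return g, removed


def connected_components(graph: StreetGraph) -> list[set[int]]:
    """Connected components as sets of node ids (largest first); isolated
    nodes form singletons."""
    import networkx as nx

    return [set(c) for c in sorted(
        nx.connected_components(graph.to_networkx()), key=len, reverse=True
    )]


def exclude_unreachable(graph: StreetGraph) -> tuple[list[set[int]], set[int]]:
    """Components plus the set of singleton (fully unreachable) nodes, whose
    closeness is reported as 0 rather than computed."""
    comps = connected_components(graph)
    singletons = {next(iter(c)) for c in comps if len(c) == 1}
    return comps, singletons


# ---------------------------------------------------------------------------
# exact centralities


def _scipy_csr(graph: StreetGraph) -> scipy.sparse.csr_matrix:
    """Sparse adjacency with parallel edges reduced to the minimum weight."""
    pos = {nid: i for i, nid in enumerate(graph.node_order())}
    n = graph.n
    best: dict[tuple[int, int], float] = {}
    for e in graph.edges.values():
        u, v = pos[e.u], pos[e.v]
        if u == v:
            continue
        key = (min(u, v), max(u, v))
        if key not in best or e.length < best[key]:
            best[key] = e.length
    if not best:
        return scipy.sparse.csr_matrix((n, n))
    rows, cols, vals = [], [], []
    for (u, v), w in best.items():
        rows += [u, v]
        cols += [v, u]
        vals += [w, w]
    return scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def exact_betweenness(graph: StreetGraph) -> np.ndarray:
    """Brandes betweenness over ordered pairs, aligned with ``node_order``."""
    n = graph.n
    if n == 0:
        return np.zeros(0)
    indptr, indices, weights, _ = graph.to_csr()
    c_b = np.zeros(n)
    for s in range(n):
        _, delta = _graphalg.brandes_source(indptr, indices, weights, s)
        c_b += delta
    return c_b


def exact_closeness(graph: StreetGraph) -> np.ndarray:
    """Component-wise closeness 1 / sum(d(u, .)); 0 for isolated nodes."""
    n = graph.n
    if n == 0:
        return np.zeros(0)
    dist = _cs_dijkstra(_scipy_csr(graph), directed=True)
    finite = np.where(np.isfinite(dist), dist, 0.0)
    sums = finite.sum(axis=1)
    with np.errstate(divide="ignore"):
        c_c = np.where(sums > 0, 1.0 / sums, 0.0)
    return c_c


# ---------------------------------------------------------------------------
# pivot approximation


def _pivots(n: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.choice(n, size=k, replace=False)


def approx_centrality(
    graph: StreetGraph, config: ApproximationConfig, which: str
) -> np.ndarray:
    """Pivot-sampled centrality estimate aligned with ``node_order``.

    ``which`` is ``"betweenness"`` or ``"closeness"``.  Estimators are
    unbiased under uniform sampling without replacement and reduce to the
    exact computation at k = n.
    """
    n = graph.n
    config.validate(n)
    pivots = _pivots(n, config.k, config.seed)
    if which == "betweenness":
        indptr, indices, weights, _ = graph.to_csr()
        acc = np.zeros(n)
        for s in pivots:
            _, delta = _graphalg.brandes_source(indptr, indices, weights, int(s))
            acc += delta
        return acc * (n / config.k)
    if which == "closeness":
        dist = _cs_dijkstra(_scipy_csr(graph), directed=True, indices=pivots)
        finite = np.isfinite(dist)
        # component labels let the estimator rescale per component
        comp_sum = np.where(finite, dist, 0.0).sum(axis=0)
        k_c = finite.sum(axis=0)  # pivots sharing u's component
        n_c = _component_sizes(graph)
        with np.errstate(divide="ignore", invalid="ignore"):
            s_hat = np.where(k_c > 0, (n_c / np.maximum(k_c, 1)) * comp_sum, np.inf)
            c_hat = np.where(s_hat > 0, 1.0 / s_hat, 0.0)
        c_hat = np.where(np.isfinite(c_hat), c_hat, 0.0)
        if np.any(k_c == 0):
            logger.warning("%d nodes in components without pivots: closeness set to 0",
                           int(np.sum(k_c == 0)))
        return c_hat
    raise ValueError(f"unknown centrality {which!r}")


def _component_sizes(graph: StreetGraph) -> np.ndarray:
    pos = {nid: i for i, nid in enumerate(graph.node_order())}
    out = np.zeros(graph.n)
    for comp in connected_components(graph):
        for nid in comp:
            out[pos[nid]] = len(comp)
    return out


def error_threshold(which: str, n: int, epsilon: float, diameter: float) -> float:
    """Hoeffding-type exceedance threshold for the pivot estimators.

    Single-pivot contributions are bounded by ``n - 2`` (a source's
    dependency on any node) for betweenness and by the component diameter
    for closeness sums; after the n/k scaling the additive error threshold
    is ``epsilon`` times n * (n - 2), resp. n * diameter, and
    ``P(err > threshold) <= 2 exp(-2 k epsilon^2)`` per node.
    """
    if which == "betweenness":
        return epsilon * n * max(n - 2, 1)
    if which == "closeness":
        return epsilon * n * diameter
    raise ValueError(f"unknown centrality {which!r}")


def hoeffding_bound(k: int, epsilon: float) -> float:
    return 2.0 * float(np.exp(-2.0 * k * epsilon**2))


def sweep_pivots(
    graph: StreetGraph,
    epsilon: float,
    k_values,
    which: str = "closeness",
    n_seeds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Approximation error versus pivot count k.

    For each k, ``n_seeds`` pivot samples are drawn; errors are measured
    against the exact values on the estimator's natural scale (betweenness
    score; inverse-closeness sum) and compared with the epsilon threshold.
    Returns a table (k, mean_error, max_error, exceedance_fraction, bound).
    """
    n = graph.n
    if which == "betweenness":
        exact = exact_betweenness(graph)
        diameter = 0.0
    else:
        dist = _cs_dijkstra(_scipy_csr(graph), directed=True)
        finite = np.where(np.isfinite(dist), dist, 0.0)
        exact = finite.sum(axis=1)  # inverse-closeness sums
        diameter = float(finite.max()) if finite.size else 0.0
    rows = []
    for k in k_values:
        errs = []
        exceed = 0
        total = 0
        for child in range(n_seeds):
            cfg = ApproximationConfig(k=int(k), epsilon=epsilon,
                                      seed=int(seed) * 100003 + int(k) * 1009 + child)
            est = approx_centrality(graph, cfg, which)
            if which == "closeness":
                with np.errstate(divide="ignore"):
                    est_sum = np.where(est > 0, 1.0 / est, 0.0)
                err = np.abs(est_sum - exact)
            else:
                err = np.abs(est - exact)
            thr = error_threshold(which, n, epsilon, diameter)
            errs.append(err)
            exceed += int(np.sum(err > thr))
            total += n
        err_all = np.concatenate(errs)
        rows.append({
            "k": int(k),
            "mean_error": float(err_all.mean()),
            "max_error": float(err_all.max()),
            "exceedance_fraction": exceed / total,
            "hoeffding_bound": hoeffding_bound(int(k), epsilon),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ranking, outlet assignment, correlation


def rank_nodes(scores) -> np.ndarray:
    """Average-tie fractional ranks; higher score -> higher rank."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return stats.rankdata(scores, method="average")


def assign_outlets_to_nodes(outlet_xy: np.ndarray, graph: StreetGraph) -> np.ndarray:
    """Count outlets at their Euclidean-nearest node (ties: smallest id).

    Returns per-node counts aligned with ``node_order``; counts conserve the
    outlet total.
    """
    if graph.n == 0:
        raise ValueError("empty graph")
    outlet_xy = np.asarray(outlet_xy, dtype=float).reshape(-1, 2)
    xy = graph.node_xy()
    counts = np.zeros(graph.n, dtype=np.int64)
    if len(outlet_xy) == 0:
        return counts
    tree = cKDTree(xy)
    kq = min(graph.n, 8)
    d, idx = tree.query(outlet_xy, k=kq)
    d = np.atleast_2d(d)
    idx = np.atleast_2d(idx)
    for i in range(len(outlet_xy)):
        tie = idx[i][d[i] <= d[i, 0] + 1e-9]
        counts[int(tie.min())] += 1
    return counts


def correlate(
    node_counts,
    ranks,
    method: str,
    district_id: str = "",
    metric: str = "",
) -> CorrelationResult:
    """Correlate per-node outlet counts with centrality ranks.

    Pearson is the product-moment coefficient on (count, rank); Spearman
    rank-transforms the counts first.  Constant inputs raise
    :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(node_counts, dtype=float)
    y = np.asarray(ranks, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 aligned observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError(
            f"district {district_id}: constant variable, correlation undefined"
        )
    if method == "pearson":
        r = float(stats.pearsonr(x, y).statistic)
    elif method == "spearman":
        r = float(stats.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(district_id=district_id, method=method,
                             metric=metric, r=r, n_nodes=len(x))
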