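"""Low-level shortest-path kernels shared by the distance and centrality stages.

The street graphs are undirected, sparse (mean degree 2-3) and positively
weighted, stored here in CSR form with every undirected edge present in both
directions.  Three kernels are provided:

* :func:`brandes_source` -- single-source Dijkstra with shortest-path counting
  (sigma) and Brandes dependency accumulation (delta); the building block for
  exact and pivot-approximated betweenness.
* :func:`dijkstra_nearest` -- Dijkstra with early termination on the first
  settled target node (nearest-other-outlet queries).
* :func:`sssp` -- plain single/multi-source distances (also used as a
  cross-check against :mod:`scipy.sparse.csgraph`).

Kernels are jitted with numba when available and run as plain Python loops
otherwise (identical arithmetic, just slower).

Equal-length path ties are detected with a relative tolerance of 1e-12 so
integer-valued weights (whose float sums are exact) tie robustly while
continuous jittered lengths never tie by accident.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

_INF = np.inf


def build_csr(n: int, edge_u: np.ndarray, edge_v: np.ndarray, edge_w: np.ndarray):
    """Symmetric CSR adjacency from an undirected edge list.

    Returns ``(indptr, indices, weights, edge_ids)`` where ``edge_ids[j]``
    maps each directed arc back to its undirected edge index.
    """
    edge_u = np.asarray(edge_u, dtype=np.int64)
    edge_v = np.asarray(edge_v, dtype=np.int64)
    edge_w = np.asarray(edge_w, dtype=np.float64)
    if np.any(edge_w <= 0):
        raise ValueError("edge weights must be strictly positive")
    m = len(edge_u)
    src = np.concatenate([edge_u, edge_v])
    dst = np.concatenate([edge_v, edge_u])
    wgt = np.concatenate([edge_w, edge_w])
    eid = np.concatenate([np.arange(m), np.arange(m)])
    order = np.argsort(src, kind="stable")
    src, dst, wgt, eid = src[order], dst[order], wgt[order], eid[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, dst.astype(np.int64), wgt, eid.astype(np.int64)


@njit(cache=True)
def _heap_push(heap_d, heap_v, size, d, v):
    i = size
    heap_d[i] = d
    heap_v[i] = v
    while i > 0:
        parent = (i - 1) >> 1
        if heap_d[parent] <= heap_d[i]:
            break
        heap_d[parent], heap_d[i] = heap_d[i], heap_d[parent]
        heap_v[parent], heap_v[i] = heap_v[i], heap_v[parent]
        i = parent
    return size + 1


@njit(cache=True)
def _heap_pop(heap_d, heap_v, size):
    d0 = heap_d[0]
    v0 = heap_v[0]
    size -= 1
    heap_d[0] = heap_d[size]
    heap_v[0] = heap_v[size]
    i = 0
    while True:
        left = 2 * i + 1
        right = left + 1
        smallest = i
        if left < size and heap_d[left] < heap_d[smallest]:
            smallest = left
        if right < size and heap_d[right] < heap_d[smallest]:
            smallest = right
        if smallest == i:
            break
        heap_d[smallest], heap_d[i] = heap_d[i], heap_d[smallest]
        heap_v[smallest], heap_v[i] = heap_v[i], heap_v[smallest]
        i = smallest
    return d0, v0, size


@njit(cache=True)
def _dijkstra_counting(indptr, indices, weights, s):
    """Dijkstra from ``s`` with path counting.

    Returns ``(dist, sigma, order, n_settled)`` where ``order[:n_settled]``
    lists nodes in non-decreasing settling distance.
    """
    n = indptr.shape[0] - 1
    dist = np.full(n, _INF)
    sigma = np.zeros(n)
    settled = np.zeros(n, dtype=np.uint8)
    order = np.empty(n, dtype=np.int64)
    cap = 4 * (indices.shape[0] + 4)
    heap_d = np.empty(cap)
    heap_v = np.empty(cap, dtype=np.int64)
    size = 0
    dist[s] = 0.0
    sigma[s] = 1.0
    size = _heap_push(heap_d, heap_v, size, 0.0, s)
    n_settled = 0
    while size > 0:
        d, u, size = _heap_pop(heap_d, heap_v, size)
        if settled[u]:
            continue
        settled[u] = 1
        order[n_settled] = u
        n_settled += 1
        for j in range(indptr[u], indptr[u + 1]):
            v = indices[j]
            if settled[v]:
                continue
            nd = d + weights[j]
            eps = 1e-12 * (1.0 + nd)
            if nd < dist[v] - eps:
                dist[v] = nd
                sigma[v] = sigma[u]
                size = _heap_push(heap_d, heap_v, size, nd, v)
            elif nd <= dist[v] + eps:
                sigma[v] += sigma[u]
    return dist, sigma, order, n_settled


@njit(cache=True)
def brandes_source(indptr, indices, weights, s):
    """One-source Brandes pass: returns ``(dist, delta)``.

    ``delta[v]`` is the dependency of source ``s`` on ``v``, i.e.
    ``sum_t sigma_st(v) / sigma_st`` over targets ``t != s, v``.  Summing
    ``delta`` over all sources yields betweenness over ordered node pairs.
    """
    dist, sigma, order, n_settled = _dijkstra_counting(indptr, indices, weights, s)
    n = indptr.shape[0] - 1
    delta = np.zeros(n)
    for i in range(n_settled - 1, -1, -1):
        w = order[i]
        if w == s:
            continue
        coeff = (1.0 + delta[w]) / sigma[w]
        dw = dist[w]
        for j in range(indptr[w], indptr[w + 1]):
            v = indices[j]
            nd = dist[v] + weights[j]
            eps = 1e-12 * (1.0 + dw)
            # v is a shortest-path predecessor of w iff d(v) + w(v,w) == d(w)
            if nd <= dw + eps and nd >= dw - eps:
                delta[v] += sigma[v] * coeff
    delta[s] = 0.0  # the source is an endpoint, never an intermediate
    return dist, delta


@njit(cache=True)
def dijkstra_nearest(indptr, indices, weights, s, is_target):
    """Distance from ``s`` to the nearest node flagged in ``is_target``
    (excluding ``s`` itself); inf when unreachable."""
    n = indptr.shape[0] - 1
    dist = np.full(n, _INF)
    settled = np.zeros(n, dtype=np.uint8)
    cap = 4 * (indices.shape[0] + 4)
    heap_d = np.empty(cap)
    heap_v = np.empty(cap, dtype=np.int64)
    size = 0
    dist[s] = 0.0
    size = _heap_push(heap_d, heap_v, size, 0.0, s)
    while size > 0:
        d, u, size = _heap_pop(heap_d, heap_v, size)
        if settled[u]:
            continue
        settled[u] = 1
        if is_target[u] and u != s:
            return d
        for j in range(indptr[u], indptr[u + 1]):
            v = indices[j]
            if settled[v]:
                continue
            nd = d + weights[j]
            if nd < dist[v]:
                dist[v] = nd
                size = _heap_push(heap_d, heap_v, size, nd, v)
    return _INF


@njit(cache=True)
def sssp(indptr, indices, weights, sources):
    """Multi-source Dijkstra: distance to the nearest of ``sources``."""
    n = indptr.shape[0] - 1
    dist = np.full(n, _INF)
    settled = np.zeros(n, dtype=np.uint8)
    cap = 4 * (indices.shape[0] + 4) + sources.shape[0]
    heap_d = np.empty(cap)
    heap_v = np.empty(cap, dtype=np.int64)
    size = 0
    for i in range(sources.shape[0]):
        s = sources[i]
        dist[s] = 0.0
        size = _heap_push(heap_d, heap_v, size, 0.0, s)
    while size > 0:
        d, u, size = _heap_pop(heap_d, heap_v, size)
        if settled[u]:
            continue
        settled[u] = 1
        for j in range(indptr[u], indptr[u + 1]):
            v = indices[j]
            if settled[v]:
                continue
            nd = d + weights[j]
            if nd < dist[v]:
                dist[v] = nd
                size = _heap_push(heap_d, heap_v, size, nd, v)
    return dist
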