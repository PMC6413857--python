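"""Independent brute-force oracles used to validate graph algorithms.

These deliberately avoid the implementation paths they check: union-find for
components, recursive simple-path enumeration for shortest paths, and a
Floyd-Warshall-style cubic path-counting scheme for centralities.
"""

import itertools

import numpy as np


def union_find_components(n, edges):
    """Connected components of an n-node graph via union-find."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in edges:
        ra, rb = find(u), find(v)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for node in range(n):
        comps.setdefault(find(node), set()).add(node)
    return sorted(comps.values(), key=lambda c: (-len(c), min(c)))


def enumerate_shortest_paths(adj, source):
    """Single-source distances by exhaustive simple-path enumeration.

    ``adj``: dict node -> list of (neighbor, weight).  Exponential; for
    n <= 12 only.
    """
    nodes = list(adj)
    best = {v: np.inf for v in nodes}
    best[source] = 0.0

    def walk(u, dist, visited):
        for v, w in adj[u]:
            if v in visited:
                continue
            nd = dist + w
            if nd < best[v]:
                best[v] = nd
            # keep exploring: a longer prefix may still reach others shorter
            walk(v, nd, visited | {v})

    walk(source, 0.0, {source})
    return best


def fw_centralities(n, edges):
    """Exact betweenness/closeness via cubic all-pairs path counting.

    ``edges``: list of (u, v, w) undirected.  Returns (c_b, c_c) where
    betweenness sums sigma_st(v)/sigma_st over ordered pairs s != t != v and
    closeness is 1/sum of distances within the component (0 for isolated
    nodes).  Path counts come from Floyd-Warshall-style relaxation, an
    algorithm disjoint from Brandes accumulation.
    """
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    np.fill_diagonal(dist, 0.0)
    np.fill_diagonal(sigma, 1.0)
    for u, v, w in edges:
        if w < dist[u, v]:
            dist[u, v] = dist[v, u] = w
            sigma[u, v] = sigma[v, u] = 1.0
        elif w == dist[u, v]:
            sigma[u, v] += 1.0
            sigma[v, u] = sigma[u, v]
    for k in range(n):
        for i in range(n):
            if not np.isfinite(dist[i, k]):
                continue
            for j in range(n):
                if i == j or k == i or k == j:
                    continue
                nd = dist[i, k] + dist[k, j]
                if not np.isfinite(nd):
                    continue
                if nd < dist[i, j] - 1e-12:
                    dist[i, j] = nd
                    sigma[i, j] = sigma[i, k] * sigma[k, j]
                elif abs(nd - dist[i, j]) <= 1e-12:
                    sigma[i, j] += sigma[i, k] * sigma[k, j]
    # the relaxation above can multi-count paths through several pivots;
    # recompute sigma cleanly by dynamic programming over distance order
    sigma = _count_paths(n, edges, dist)
    c_b = np.zeros(n)
    with np.errstate(invalid="ignore"):
        for s, t in itertools.permutations(range(n), 2):
            if not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                continue
            on_path = (
                np.abs(dist[s, :] + dist[:, t] - dist[s, t])
                <= 1e-9 * (1 + dist[s, t])
            )
            on_path[s] = on_path[t] = False
            on_path &= np.isfinite(dist[s, :]) & np.isfinite(dist[:, t])
            c_b[on_path] += (
                sigma[s, on_path] * sigma[on_path, t] / sigma[s, t]
            )
    finite = np.where(np.isfinite(dist), dist, 0.0)
    sums = finite.sum(axis=1)
    c_c = np.where(sums > 0, 1.0 / np.where(sums > 0, sums, 1.0), 0.0)
    return c_b, c_c


def _count_paths(n, edges, dist):
    """sigma[s, t] = number of shortest s-t paths, by DP in distance order."""
    adj = {v: [] for v in range(n)}
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(dist[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            total = 0.0
            for u, w in adj[t]:
                if abs(dist[s, u] + w - dist[s, t]) <= 1e-9 * (1 + dist[s, t]):
                    total += sigma[s, u]
            sigma[s, t] = total
    return sigma
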