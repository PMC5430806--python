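"""Independent brute-force oracles for centrality and tallying checks.

Deliberately naive: Floyd-Warshall all-pairs distances by triple loop,
geodesic enumeration by DFS over the shortest-path DAG, eigenvector by
dense symmetric eigendecomposition. Nothing here shares code with the
package's implementation paths.
"""

import numpy as np

EPS = 1e-12


def distance_matrix(nodes, edges):
    """Floyd-Warshall over cost = 1/weight. ``edges``: {(u,v): w}."""
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for (u, v), w in edges.items():
        d = 1.0 / w
        D[idx[u], idx[v]] = min(D[idx[u], idx[v]], d)
        D[idx[v], idx[u]] = min(D[idx[v], idx[u]], d)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D, idx


def brute_closeness(nodes, edges):
    """1 / sum of geodesic distances to reachable others (isolates 0)."""
    D, idx = distance_matrix(nodes, edges)
    out = {}
    for u in nodes:
        row = D[idx[u]]
        total = sum(row[i] for i in range(len(nodes))
                    if i != idx[u] and np.isfinite(row[i]))
        out[u] = 1.0 / total if total > 0 else 0.0
    return out


def _geodesic_paths(u, t, nodes, edges, D, idx, adj):
    """All shortest paths u->t by DFS over distance-certified edges."""
    if u == t:
        return [[t]]
    paths = []
    for v, w in adj[u]:
        if abs(D[idx[u], idx[t]] - (1.0 / w + D[idx[v], idx[t]])) < EPS * max(
                1.0, D[idx[u], idx[t]]):
            for tail in _geodesic_paths(v, t, nodes, edges, D, idx, adj):
                paths.append([u] + tail)
    return paths


def brute_betweenness(nodes, edges):
    """Fractional geodesic counts through internal nodes, pairs once."""
    D, idx = distance_matrix(nodes, edges)
    adj = {n: [] for n in nodes}
    for (u, v), w in edges.items():
        adj[u].append((v, w))
        adj[v].append((u, w))
    score = {n: 0.0 for n in nodes}
    ns = list(nodes)
    for i in range(len(ns)):
        for j in range(i + 1, len(ns)):
            s, t = ns[i], ns[j]
            if not np.isfinite(D[idx[s], idx[t]]):
                continue
            paths = _geodesic_paths(s, t, nodes, edges, D, idx, adj)
            for p in paths:
                for internal in p[1:-1]:
                    score[internal] += 1.0 / len(paths)
    return score


def brute_eigenvector(nodes, edges):
    """Leading eigenvector of the weighted adjacency on the largest
    component, max-normalized; others 0."""
    # components by label propagation over edges
    parent = {n: n for n in nodes}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for (u, v) in edges:
        parent[find(u)] = find(v)
    comps = {}
    for n in nodes:
        comps.setdefault(find(n), []).append(n)
    comp = max(comps.values(), key=len)
    idx = {n: i for i, n in enumerate(comp)}
    A = np.zeros((len(comp), len(comp)))
    for (u, v), w in edges.items():
        if u in idx and v in idx:
            A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    vals, vecs = np.linalg.eigh(A)
    lead = np.abs(vecs[:, np.argmax(vals)])
    lead = lead / lead.max()
    out = {n: 0.0 for n in nodes}
    out.update({n: float(lead[idx[n]]) for n in comp})
    return out, float(np.max(vals))


def random_connected_graph(rng, n_max=8, n_min=3):
    """Random connected weighted graph as (nodes, {(u,v): w})."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        nodes = [f"v{i}" for i in range(n)]
        edges = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.55:
                    edges[(nodes[i], nodes[j])] = float(rng.uniform(0.2, 3.0))
        # connectivity via the union-find in brute_eigenvector's style
        parent = {x: x for x in nodes}

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for (u, v) in edges:
            parent[find(u)] = find(v)
        if len({find(x) for x in nodes}) == 1:
            return nodes, edges
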