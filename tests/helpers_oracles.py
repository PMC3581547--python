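"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — all-pairs BFS, exhaustive shortest-path
enumeration, triple loops, full permutation enumeration — and shares no code
with the implementation it checks.
"""
from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def enumerate_shortest_paths(adj: dict, dist_s: dict, s, t):
    """All shortest s->t paths, found by walking predecessors back from t."""
    if s == t:
        return [[s]]
    paths = []
    for w in adj[t]:
        if dist_s.get(w, -1) == dist_s[t] - 1:
            for path in enumerate_shortest_paths(adj, dist_s, s, w):
                paths.append(path + [t])
    return paths


def oracle_node_metrics(adj: dict, mirna_nodes: set) -> dict:
    """All ten per-node topology metrics by brute force.

    ``adj`` maps node -> iterable of neighbors (undirected, both directions
    present). Metrics follow the conventions of the implementation under test:
    per-component paths, isolated nodes zeroed, betweenness normalized by
    (n_c-1)(n_c-2)/2, topological coefficient 0 for degree <= 1.
    """
    nodes = sorted(adj)
    degree = {v: len(set(adj[v])) for v in nodes}
    dist = {v: bfs_distances(adj, v) for v in nodes}

    # connected components from BFS reachability
    components, seen = [], set()
    for v in nodes:
        if v not in seen:
            comp = sorted(dist[v])
            components.append(comp)
            seen.update(comp)

    out = {
        v: {
            "degree": float(degree[v]),
            "out_edge_count": float(degree[v] if v in mirna_nodes else 0),
            "neighborhood_connectivity": (
                float(np.mean([degree[w] for w in set(adj[v])])) if degree[v] else 0.0
            ),
            "avg_shortest_path": 0.0,
            "closeness": 0.0,
            "eccentricity": 0.0,
            "radiality": 0.0,
            "betweenness": 0.0,
            "stress": 0.0,
            "topological_coefficient": 0.0,
        }
        for v in nodes
    }

    for comp in components:
        n = len(comp)
        if n == 1:
            continue
        diam = max(dist[s][t] for s in comp for t in comp)
        for v in comp:
            ds = [dist[v][w] for w in comp if w != v]
            asp = sum(ds) / len(ds)
            out[v]["avg_shortest_path"] = asp
            out[v]["closeness"] = 1.0 / asp
            out[v]["eccentricity"] = float(max(ds))
            out[v]["radiality"] = (diam + 1 - asp) / diam
        norm = (n - 1) * (n - 2) / 2.0
        for s, t in itertools.combinations(comp, 2):
            paths = enumerate_shortest_paths(adj, dist[s], s, t)
            for v in comp:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                out[v]["stress"] += through
                if norm > 0:
                    out[v]["betweenness"] += through / len(paths) / norm

    for v in nodes:
        if degree[v] <= 1:
            continue
        nv = set(adj[v])
        partners = {}
        for w in nodes:
            if w == v:
                continue
            shared = len(nv & set(adj[w]))
            if shared:
                partners[w] = shared + (1 if w in nv else 0)
        if partners:
            out[v]["topological_coefficient"] = (
                sum(partners.values()) / len(partners) / degree[v]
            )
    return out


def brute_overlap(cnvs, mirnas, policy: str) -> dict:
    """All-pairs O(n*m) interval-overlap oracle."""
    result = {c.locus_id: set() for c in cnvs}
    for cnv in cnvs:
        for mir in mirnas:
            if policy == "full_containment":
                hit = cnv.interval.contains(mir.interval)
            else:
                hit = cnv.interval.overlaps(mir.interval)
            if hit:
                result[cnv.locus_id].add(mir.mirna_id)
    return result


def ecdf_gap(x, y) -> float:
    x = np.sort(np.asarray(x, float))
    y = np.sort(np.asarray(y, float))
    grid = np.concatenate([x, y])
    fx = np.searchsorted(x, grid, side="right") / len(x)
    fy = np.searchsorted(y, grid, side="right") / len(y)
    return float(np.abs(fx - fy).max())


def enumerate_ks_exact_p(x, y) -> float:
    """Full enumeration of all C(n+m, n) label assignments."""
    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    n = len(x)
    d_obs = ecdf_gap(x, y)
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        xs = pooled[list(combo)]
        ys = pooled[[i for i in range(len(pooled)) if i not in combo]]
        total += 1
        if ecdf_gap(xs, ys) >= d_obs - 1e-12:
            hits += 1
    return hits / total


def brute_inverse_pairs(calls, edges) -> set:
    """Triple-loop oracle returning (mirna, gene, mirna_state, gene_state)."""
    edge_pairs = {(e.mirna_id, e.gene_symbol) for e in edges}
    found = set()
    for a in calls:
        for b in calls:
            if a.element_kind.value != "MIRNA" or b.element_kind.value != "GENE":
                continue
            if a.state.value == b.state.value:
                continue
            if (a.element_id, b.element_id) in edge_pairs:
                found.add((a.element_id, b.element_id, a.state.value, b.state.value))
    return found
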