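"""miRNA-target bipartite network: construction, topology metrics, hub ranking.

Edges are semantically directed miRNA -> gene (a miRNA represses its target),
but all topology metrics are computed on the undirected view, following the
convention of the network-analysis tooling whose metric set this module
reproduces (average shortest path, closeness = 1/asp, eccentricity,
neighborhood connectivity, radiality, betweenness, stress, topological
coefficient). The directed edge count survives as ``out_edge_count``.

Shortest-path metrics are per connected component with unit edge weights;
isolated nodes get 0 for every path-based metric, and betweenness is
normalized by (n-1)(n-2)/2 within each node's component.
"""
from __future__ import annotations

import enum
import logging
from collections import Counter, deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tables_io import GeneSet, PredictionRow, Region

log = logging.getLogger(__name__)

__all__ = [
    "Evidence",
    "InteractionEdge",
    "BipartiteNetwork",
    "GlobalProperties",
    "DEFAULT_SOURCES",
    "NODE_METRICS",
    "consensus_targets",
    "restrict_to_gene_set",
    "build_bipartite",
    "node_properties",
    "global_properties",
    "rank_hubs",
    "degree_distribution_fit",
    "fit_power_law",
]

#: the four prediction programs whose agreement defines a consensus target
DEFAULT_SOURCES = frozenset({"miranda", "mirdb", "mirwalk", "targetscan"})

#: the ten per-node topology metrics of NodePropertyTable, in column order
NODE_METRICS = (
    "degree",
    "avg_shortest_path",
    "closeness",
    "eccentricity",
    "neighborhood_connectivity",
    "radiality",
    "betweenness",
    "stress",
    "topological_coefficient",
    "out_edge_count",
)


class Evidence(str, enum.Enum):
    VALIDATED = "VALIDATED"
    PREDICTED = "PREDICTED"


@dataclass(frozen=True)
class InteractionEdge:
    """A miRNA -> gene link with its evidence trail."""

    mirna_id: str
    gene_symbol: str
    evidence: Evidence
    supporting_sources: frozenset[str] = frozenset()


@dataclass
class BipartiteNetwork:
    """A miRNA/gene bipartite graph; node sets are disjoint, no self loops."""

    mirna_nodes: set[str]
    gene_nodes: set[str]
    edges: dict[tuple[str, str], InteractionEdge] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clash = self.mirna_nodes & self.gene_nodes
        if clash:
            raise ValueError(
                "id(s) appear on both sides of the bipartite network: " + ", ".join(sorted(clash))
            )
        for (mirna, gene), edge in self.edges.items():
            if mirna not in self.mirna_nodes or gene not in self.gene_nodes:
                raise ValueError(f"edge ({mirna}, {gene}) has an undeclared endpoint")
            if edge.mirna_id != mirna or edge.gene_symbol != gene:
                raise ValueError(f"edge key ({mirna}, {gene}) disagrees with its record")

    @property
    def n_nodes(self) -> int:
        return len(self.mirna_nodes) + len(self.gene_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for (m, g) in self.edges if m == node or g == node)

    def to_networkx(self) -> nx.Graph:
        """Undirected view; node attr ``kind`` in {mirna, gene}, edge attrs
        ``evidence`` and comma-joined ``sources``."""
        graph = nx.Graph()
        for node in sorted(self.mirna_nodes):
            graph.add_node(node, kind="mirna")
        for node in sorted(self.gene_nodes):
            graph.add_node(node, kind="gene")
        for (mirna, gene), edge in self.edges.items():
            graph.add_edge(mirna, gene, evidence=edge.evidence.value,
                           sources=",".join(sorted(edge.supporting_sources)))
        return graph

    def remove_node(self, node: str) -> "BipartiteNetwork":
        """Copy of the network without ``node`` and its incident edges."""
        if node not in self.mirna_nodes and node not in self.gene_nodes:
            raise KeyError(f"node {node!r} not in network")
        return BipartiteNetwork(
            self.mirna_nodes - {node},
            self.gene_nodes - {node},
            {k: e for k, e in self.edges.items() if node not in k},
        )


@dataclass(frozen=True)
class GlobalProperties:
    diameter: int
    characteristic_path_length: float
    density: float
    connected_components: int
    isolated_nodes: int


def consensus_targets(
    predictions: list[PredictionRow],
    required_sources: frozenset[str] | set[str] = DEFAULT_SOURCES,
    min_seed: int = 7,
    region: Region = Region.UTR3,
) -> list[InteractionEdge]:
    """Cross-database consensus filter plus validated-interaction pass-through.

    A (miRNA, gene) pair becomes a PREDICTED edge iff every required source
    has a row for it in the required region with a seed match of at least
    ``min_seed`` nucleotides. Any validated row yields a VALIDATED edge for
    its pair regardless of consensus, and VALIDATED supersedes PREDICTED.
    """
    required = frozenset(s.lower() for s in required_sources)
    if not required:
        raise ValueError("required_sources must be non-empty")
    qualifying: dict[tuple[str, str], set[str]] = {}
    validated: set[tuple[str, str]] = set()
    for row in predictions:
        pair = (row.mirna_id, row.gene_symbol)
        if row.validated:
            validated.add(pair)
        elif (
            row.source_id in required
            and row.region is region
            and row.seed_match_len >= min_seed
        ):
            qualifying.setdefault(pair, set()).add(row.source_id)
    edges = []
    for pair in sorted(validated | set(qualifying)):
        sources = qualifying.get(pair, set())
        if pair in validated:
            edges.append(InteractionEdge(*pair, Evidence.VALIDATED, frozenset(sources)))
        elif sources >= required:
            edges.append(InteractionEdge(*pair, Evidence.PREDICTED, frozenset(sources)))
    return edges


def restrict_to_gene_set(edges: list[InteractionEdge], master: GeneSet) -> list[InteractionEdge]:
    """Keep edges whose target gene belongs to the master disease-gene list."""
    if not master.symbols:
        raise ValueError("master gene set is empty")
    kept = [e for e in edges if e.gene_symbol in master]
    if not kept and edges:
        log.warning("restrict_to_gene_set: no edge targets a gene in %r", master.name)
    return kept


def build_bipartite(edges: list[InteractionEdge]) -> BipartiteNetwork:
    """Assemble a network from edges; duplicate pairs merge (VALIDATED wins)."""
    merged: dict[tuple[str, str], InteractionEdge] = {}
    for edge in edges:
        key = (edge.mirna_id, edge.gene_symbol)
        prev = merged.get(key)
        if prev is None:
            merged[key] = edge
        else:
            evidence = (
                Evidence.VALIDATED
                if Evidence.VALIDATED in (prev.evidence, edge.evidence)
                else Evidence.PREDICTED
            )
            merged[key] = InteractionEdge(
                *key, evidence, prev.supporting_sources | edge.supporting_sources
            )
    mirnas = {m for m, _ in merged}
    genes = {g for _, g in merged}
    return BipartiteNetwork(mirnas, genes, merged)


# --------------------------------------------------------------------------
# Topology metrics
# --------------------------------------------------------------------------

def _bfs_dist_sigma(adj: list[list[int]], source: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-weight BFS returning distances and shortest-path counts from source."""
    dist = np.full(n, -1, dtype=np.int64)
    sigma = np.zeros(n, dtype=np.float64)
    dist[source] = 0
    sigma[source] = 1.0
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in adj[v]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
            if dist[w] == dist[v] + 1:
                sigma[w] += sigma[v]
    return dist, sigma


def _component_path_metrics(nodes: list[str], adj_map: dict[str, list[str]]):
    """Distance and path-count matrices for one connected component."""
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = [[index[w] for w in adj_map[v]] for v in nodes]
    dist = np.empty((n, n), dtype=np.int64)
    sigma = np.empty((n, n), dtype=np.float64)
    for i in range(n):
        dist[i], sigma[i] = _bfs_dist_sigma(adj, i, n)
    return dist, sigma


def node_properties(net: BipartiteNetwork) -> pd.DataFrame:
    """The ten per-node topology metrics, one row per node.

    Definitions (undirected view, unit weights, per component):

    - avg_shortest_path(v): mean d(v, w) over reachable w != v
    - closeness(v) = 1 / avg_shortest_path(v)
    - eccentricity(v) = max d(v, w) over reachable w
    - neighborhood_connectivity(v) = mean degree of v's neighbors
    - radiality(v) = (diam_c + 1 - asp(v)) / diam_c, diam_c = component diameter
    - betweenness(v): sum over pairs s < t (same component, both != v) of
      sigma_st(v)/sigma_st, divided by (n_c-1)(n_c-2)/2
    - stress(v): number of shortest s-t paths (s != t != v) passing through v
    - topological_coefficient(v): mean over nodes w sharing >= 1 neighbor with
      v of J(v, w)/degree(v), J = #shared neighbors (+1 if v, w adjacent);
      0 for nodes of degree <= 1 or with no such partner
    - out_edge_count: directed miRNA -> gene edges leaving v (0 for genes)

    Isolated nodes get 0 for every path-based metric.
    """
    graph = net.to_networkx()
    all_nodes = list(graph.nodes)
    table = pd.DataFrame(0.0, index=all_nodes, columns=list(NODE_METRICS))
    degrees = dict(graph.degree)
    adj_map = {v: sorted(graph.neighbors(v)) for v in all_nodes}

    for v in all_nodes:
        table.loc[v, "degree"] = degrees[v]
        table.loc[v, "out_edge_count"] = degrees[v] if v in net.mirna_nodes else 0
        if degrees[v] > 0:
            table.loc[v, "neighborhood_connectivity"] = float(
                np.mean([degrees[w] for w in adj_map[v]])
            )

    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        n = len(nodes)
        if n == 1:
            continue  # singleton: path metrics stay 0 by convention
        dist, sigma = _component_path_metrics(nodes, adj_map)
        diam = int(dist.max())
        off = ~np.eye(n, dtype=bool)
        asp = dist.sum(axis=1) / (n - 1)
        ecc = dist.max(axis=1)
        betweenness = np.zeros(n)
        stress = np.zeros(n)
        norm_pairs = (n - 1) * (n - 2) / 2.0
        for i in range(n):
            # pairs (s, t) with v=i strictly between: d(s,v)+d(v,t) == d(s,t)
            through = dist[:, i][:, None] + dist[i, :][None, :] == dist
            through &= off
            through[i, :] = False
            through[:, i] = False
            paths = sigma[:, i][:, None] * sigma[i, :][None, :]
            stress[i] = paths[through].sum() / 2.0
            if norm_pairs > 0:
                betweenness[i] = (paths[through] / sigma[through]).sum() / 2.0 / norm_pairs
        for i, v in enumerate(nodes):
            table.loc[v, "avg_shortest_path"] = asp[i]
            table.loc[v, "closeness"] = 1.0 / asp[i]
            table.loc[v, "eccentricity"] = float(ecc[i])
            table.loc[v, "radiality"] = (diam + 1 - asp[i]) / diam
            table.loc[v, "betweenness"] = betweenness[i]
            table.loc[v, "stress"] = stress[i]

    for v in all_nodes:
        table.loc[v, "topological_coefficient"] = _topological_coefficient(v, adj_map, degrees)
    return table


def _topological_coefficient(v: str, adj_map: dict[str, list[str]], degrees: dict[str, int]) -> float:
    if degrees[v] <= 1:
        return 0.0
    neighbors = set(adj_map[v])
    shared: dict[str, int] = Counter()
    for u in neighbors:
        for w in adj_map[u]:
            if w != v:
                shared[w] += 1
    if not shared:
        return 0.0
    total = sum(count + (1 if w in neighbors else 0) for w, count in shared.items())
    return total / len(shared) / degrees[v]


def global_properties(net: BipartiteNetwork) -> GlobalProperties:
    """Diameter, characteristic path length, density, components, isolated nodes.

    The diameter is the largest finite pairwise distance (0 for an edgeless
    graph); the characteristic path length averages over all finite nonzero
    pairwise distances; density = 2E / (N(N-1)).
    """
    graph = net.to_networkx()
    n = graph.number_of_nodes()
    e = graph.number_of_edges()
    diameter = 0
    total = 0
    n_pairs = 0
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            continue
        sub = graph.subgraph(nodes)
        for _v, dists in nx.all_pairs_shortest_path_length(sub):
            for w, d in dists.items():
                if d > 0:
                    total += d
                    n_pairs += 1
                    diameter = max(diameter, d)
    cpl = total / n_pairs if n_pairs else 0.0
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    return GlobalProperties(
        diameter=diameter,
        characteristic_path_length=cpl,
        density=density,
        connected_components=nx.number_connected_components(graph),
        isolated_nodes=sum(1 for _v, d in graph.degree if d == 0),
    )


def rank_hubs(net: BipartiteNetwork, k: int = 10, all_nodes: bool = False) -> list[tuple[str, int]]:
    """Top-k nodes by degree (descending; ties broken lexicographically).

    Ranking is over miRNA-side nodes by default — the regulators are the
    actionable hubs — with ``all_nodes=True`` widening to both partitions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    graph = net.to_networkx()
    candidates = list(graph.nodes) if all_nodes else sorted(net.mirna_nodes)
    ranked = sorted(candidates, key=lambda v: (-graph.degree(v), v))
    top = [(v, graph.degree(v)) for v in ranked[: min(k, len(ranked))]]
    if len(top) >= 2 and len(ranked) > len(top):
        cutoff = top[-1][1]
        if graph.degree(ranked[len(top)]) == cutoff:
            log.info("rank_hubs: tie at degree %d broken lexicographically", cutoff)
    return top


def fit_power_law(degree_counts: dict[int, int]) -> tuple[float, float]:
    """Descriptive power-law fit of a degree histogram.

    Least-squares line on log10(count) vs log10(degree) over positive-count
    bins with degree >= 1; returns (exponent, r_squared) where the exponent is
    the negated slope. This is a descriptive log-log regression, not a
    maximum-likelihood fit.
    """
    points = [(k, c) for k, c in degree_counts.items() if k >= 1 and c > 0]
    if len(points) < 3:
        raise ValueError("need >= 3 distinct positive degree values for a power-law fit")
    x = np.log10([k for k, _c in points])
    y = np.log10([c for _k, c in points])
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(-slope), r_squared


def degree_distribution_fit(net: BipartiteNetwork) -> tuple[float, float]:
    """Power-law exponent and R^2 of the network's degree distribution."""
    graph = net.to_networkx()
    counts = Counter(d for _v, d in graph.degree if d > 0)
    return fit_power_law(dict(counts))
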