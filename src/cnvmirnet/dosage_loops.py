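"""Dosage intersections, patient-level inverse pairs, TF loops, biogenesis subnetwork.

Dosage logic: a miRNA represses its targets, so deleting the miRNA releases
them (predicted dosage/expression INCREASE) while duplicating it deepens
repression (DECREASE). Genes targeted only by miRNAs in loci seen both deleted
and duplicated in different individuals can FLUCTUATE; genes targeted by all
three miRNA classes are CENTRAL; the remaining pairwise-only intersections are
direction-unresolved and labelled MIXED.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .regnet import BipartiteNetwork, InteractionEdge, build_bipartite
from .tables_io import (
    CallState,
    CnvState,
    ElementKind,
    GeneSet,
    IndividualCnvCall,
    TfRegulon,
)

log = logging.getLogger(__name__)

__all__ = [
    "DosageLabel",
    "VENN_REGIONS",
    "VennPartition",
    "InversePair",
    "LoopMode",
    "TfLoop",
    "TfLoopSummary",
    "MACHINERY_GENES",
    "dosage_partition",
    "find_inverse_pairs",
    "assemble_tf_loops",
    "biogenesis_subnetwork",
]

#: miRNA biogenesis / processing machinery (legacy symbols kept as published)
MACHINERY_GENES = GeneSet(
    "mirna_biogenesis_machinery",
    {
        "AGO1", "AGO2", "DGCR8", "DICER1", "FMR1", "GEMIN3", "GEMIN4",
        "HIWI", "P68", "P72", "RNASEN", "TARBP2", "XPO5",
    },
)


class DosageLabel(str, enum.Enum):
    INCREASE = "INCREASE"
    DECREASE = "DECREASE"
    FLUCTUATE = "FLUCTUATE"
    CENTRAL = "CENTRAL"
    MIXED = "MIXED"


#: the 7 regions of the three-set intersection, keyed by the contributing states
VENN_REGIONS = (
    "deleted_only",
    "duplicated_only",
    "deleted_duplicated_only",
    "deleted_and_duplicated",
    "deleted_and_deldup",
    "duplicated_and_deldup",
    "central",
)

_REGION_LABELS = {
    "deleted_only": DosageLabel.INCREASE,
    "duplicated_only": DosageLabel.DECREASE,
    "deleted_duplicated_only": DosageLabel.FLUCTUATE,
    "deleted_and_duplicated": DosageLabel.MIXED,
    "deleted_and_deldup": DosageLabel.MIXED,
    "duplicated_and_deldup": DosageLabel.MIXED,
    "central": DosageLabel.CENTRAL,
}


@dataclass
class VennPartition:
    """Disjoint 7-region partition of all targeted genes with dosage labels."""

    regions: dict[str, set[str]]
    labels: dict[str, DosageLabel] = field(default_factory=lambda: dict(_REGION_LABELS))

    def sizes(self) -> dict[str, int]:
        return {region: len(self.regions[region]) for region in VENN_REGIONS}

    def all_genes(self) -> set[str]:
        return set().union(*self.regions.values()) if self.regions else set()


def dosage_partition(targets_by_state: dict[CnvState, set[str]]) -> VennPartition:
    """Partition targeted genes by which miRNA CNV classes target them."""
    deleted = set(targets_by_state.get(CnvState.DELETED, set()))
    duplicated = set(targets_by_state.get(CnvState.DUPLICATED, set()))
    deldup = set(targets_by_state.get(CnvState.DELETED_DUPLICATED, set()))
    regions = {
        "deleted_only": deleted - duplicated - deldup,
        "duplicated_only": duplicated - deleted - deldup,
        "deleted_duplicated_only": deldup - deleted - duplicated,
        "deleted_and_duplicated": (deleted & duplicated) - deldup,
        "deleted_and_deldup": (deleted & deldup) - duplicated,
        "duplicated_and_deldup": (duplicated & deldup) - deleted,
        "central": deleted & duplicated & deldup,
    }
    return VennPartition(regions)


@dataclass(frozen=True)
class InversePair:
    """A miRNA and one of its targets carried in opposite CNV states."""

    mirna_id: str
    gene_symbol: str
    mirna_state: CallState
    gene_state: CallState
    mirna_individuals: frozenset[str]
    gene_individuals: frozenset[str]

    def __post_init__(self) -> None:
        if self.mirna_state is self.gene_state:
            raise ValueError("inverse pair requires opposite miRNA/gene states")


def find_inverse_pairs(
    calls: list[IndividualCnvCall],
    edges: list[InteractionEdge],
    hub_mirnas: set[str] | None = None,
) -> list[InversePair]:
    """Detect miRNA/target pairs carried in opposite CNV states across individuals.

    A pair (m, g) is emitted when some individual carries miRNA m in one state,
    some (other or same) individual carries gene g in the opposite state, and
    (m, g) is an edge of the network. Both orientations are emitted.
    ``hub_mirnas`` optionally restricts the miRNA side (e.g. to the top hubs).
    Output is sorted and independent of the input order of calls and edges.
    """
    edge_pairs = {(e.mirna_id, e.gene_symbol) for e in edges}
    mirna_calls: dict[tuple[str, CallState], set[str]] = {}
    gene_calls: dict[tuple[str, CallState], set[str]] = {}
    for call in calls:
        bucket = mirna_calls if call.element_kind is ElementKind.MIRNA else gene_calls
        bucket.setdefault((call.element_id, call.state), set()).add(call.individual_id)
    opposite = {CallState.DELETED: CallState.DUPLICATED,
                CallState.DUPLICATED: CallState.DELETED}
    pairs = []
    for (mirna, m_state), m_inds in mirna_calls.items():
        if hub_mirnas is not None and mirna not in hub_mirnas:
            continue
        g_state = opposite[m_state]
        for (gene, state), g_inds in gene_calls.items():
            if state is g_state and (mirna, gene) in edge_pairs:
                pairs.append(
                    InversePair(mirna, gene, m_state, g_state,
                                frozenset(m_inds), frozenset(g_inds))
                )
    pairs.sort(key=lambda p: (p.mirna_id, p.gene_symbol, p.mirna_state.value))
    return pairs


class LoopMode(str, enum.Enum):
    DIRECT = "DIRECT"
    TF_MEDIATED = "TF_MEDIATED"
    DUAL = "DUAL"


@dataclass(frozen=True)
class TfLoop:
    mirna_id: str
    tf_id: str | None  # None for DIRECT records
    mode: LoopMode
    affected_genes: frozenset[str]


@dataclass
class TfLoopSummary:
    """Per-TF disease-gene counts and overall coverage of the disease targets."""

    per_tf_counts: dict[str, int]
    covered_genes: set[str]
    coverage_fraction: float  # |covered| / |disease genes targeted or regulated|
    n_disease_targets: int


def assemble_tf_loops(
    mirna_gene_edges: list[InteractionEdge],
    mirna_tf_edges: list[InteractionEdge],
    regulons: list[TfRegulon],
    disease_genes: GeneSet,
) -> tuple[list[TfLoop], TfLoopSummary]:
    """Assemble miRNA / TF / target-gene regulatory loops.

    For every miRNA -> TF edge, the TF-mediated loop affects the disease genes
    in the TF's regulon; genes the miRNA also targets directly upgrade the loop
    to DUAL (carrying only the doubly-hit genes). DIRECT records enumerate
    miRNA -> gene edges that pass through no TF regulon. The summary counts
    each TF's disease-gene regulon and the fraction of the network's disease
    targets covered by the union of all TF regulons.

    TF identifiers live in their own namespace: a TF lexically identical to a
    target gene symbol is kept distinct (with a warning), because TFs are
    simultaneously miRNA targets and regulators.
    """
    regulon_map = {r.tf_id: r.regulated_genes & disease_genes.symbols for r in regulons}
    gene_symbols = {e.gene_symbol for e in mirna_gene_edges}
    collisions = sorted(set(regulon_map) & gene_symbols)
    if collisions:
        log.warning(
            "TF id(s) %s also appear as target genes; treating TFs as a distinct namespace",
            ", ".join(collisions),
        )
    direct_targets: dict[str, set[str]] = {}
    for edge in mirna_gene_edges:
        direct_targets.setdefault(edge.mirna_id, set()).add(edge.gene_symbol)

    all_regulated = set().union(*regulon_map.values()) if regulon_map else set()
    loops: list[TfLoop] = []
    for edge in sorted(mirna_tf_edges, key=lambda e: (e.mirna_id, e.gene_symbol)):
        mirna, tf = edge.mirna_id, edge.gene_symbol
        if tf not in regulon_map:
            continue  # TF without a known regulon cannot close a loop
        affected = regulon_map[tf]
        loops.append(TfLoop(mirna, tf, LoopMode.TF_MEDIATED, frozenset(affected)))
        dual = affected & direct_targets.get(mirna, set())
        if dual:
            loops.append(TfLoop(mirna, tf, LoopMode.DUAL, frozenset(dual)))
    for mirna in sorted(direct_targets):
        outside = direct_targets[mirna] - all_regulated
        if outside:
            loops.append(TfLoop(mirna, None, LoopMode.DIRECT, frozenset(outside)))

    disease_targets = {g for g in gene_symbols if g in disease_genes}
    covered = all_regulated & disease_targets
    summary = TfLoopSummary(
        per_tf_counts={tf: len(genes) for tf, genes in sorted(regulon_map.items())},
        covered_genes=covered,
        coverage_fraction=(len(covered) / len(disease_targets)) if disease_targets else 0.0,
        n_disease_targets=len(disease_targets),
    )
    return loops, summary


def biogenesis_subnetwork(
    all_edges: list[InteractionEdge],
    machinery: GeneSet = MACHINERY_GENES,
) -> tuple[BipartiteNetwork, dict[str, int]]:
    """Subnetwork of edges hitting the miRNA biogenesis machinery.

    Returns the filtered bipartite network and, for every machinery gene, the
    number of distinct miRNAs targeting it (genes with no regulator are
    retained with count 0).
    """
    if not machinery.symbols:
        raise ValueError("machinery gene set is empty")
    kept = [e for e in all_edges if e.gene_symbol in machinery]
    net = build_bipartite(kept)
    net.gene_nodes |= machinery.symbols  # retain zero-regulator machinery genes
    counts = {gene: 0 for gene in sorted(machinery.symbols)}
    for edge in kept:
        counts[edge.gene_symbol] = counts.get(edge.gene_symbol, 0)
    for gene in counts:
        counts[gene] = len({e.mirna_id for e in kept if e.gene_symbol == gene})
    return net, counts
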