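"""Seeded generator of every input the pipeline consumes.

The generator emulates the statistical structure the analysis assumes: a
multi-chromosome genome on which CNV loci accumulate at per-chromosome rates
(some chromosomes enriched), miRNA genes placed uniformly, a 4-source
target-prediction compendium with controllable cross-source concordance and
planted high-degree hub miRNAs, a disease-gene list, individual-level
deletion/duplication calls, and TF regulons. Default parameter values mirror
the scale of the published autism CNV catalog this pipeline was designed
around: 24 chromosomes, 1145 catalogued CNV loci with three enriched
chromosomes, a miRNA universe of 500, and a consensus network of roughly 400
nodes / 900 edges after disease-gene restriction.

Reproducibility: one seed per bundle, split into named substreams per output
(adding an output type never perturbs the others for a fixed seed).

The ``fixture_*`` functions are deterministic synthetic stand-ins used by the
test suite: a hand-verified micro-dataset, plus locus/dosage tables constructed
to published marginal counts (they are synthetic; no real coordinates).
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mirna_mapping import OverlapPolicy, overlap_mirnas
from .tables_io import (
    CallState,
    CnvRecord,
    CnvState,
    ElementKind,
    GeneSet,
    GenomeBuild,
    GenomicInterval,
    IndividualCnvCall,
    MirnaGene,
    PredictionRow,
    Region,
    TfRegulon,
    VariationClass,
)

__all__ = [
    "SimulationConfig",
    "SimulatedBundle",
    "simulate_bundle",
    "simulate_inputs",
    "fixture_small",
    "fixture_locus_catalog",
    "fixture_dosage_sets",
    "SOURCES",
]

SOURCES = ("miranda", "mirdb", "mirwalk", "targetscan")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, name)."""
    key = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic genome / CNV / prediction generator."""

    seed: int = 0
    n_chrom: int = 24
    chrom_lengths: list[int] | None = None  # default: 250 Mb down to ~50 Mb
    n_cnvs: int = 1145
    enriched_chroms: dict[str, float] = field(
        default_factory=lambda: {"chr15": 3.0, "chr16": 3.0, "chr22": 3.0}
    )
    class_probs: dict[VariationClass, float] = field(
        default_factory=lambda: {
            VariationClass.DELETION: 0.40,
            VariationClass.DUPLICATION: 0.30,
            VariationClass.BOTH: 0.30,
        }
    )
    study_count_geom_p: float = 0.55  # shifted geometric, support >= study_count_min
    study_count_min: int = 1
    cnv_length_range: tuple[int, int] = (200_000, 2_500_000)
    n_mirnas: int = 500
    mirna_length_bp: int = 80
    n_genes: int = 1000
    gene_length_bp: int = 20_000
    disease_gene_fraction: float = 0.35
    n_planted_hubs: int = 10
    hub_target_count: int = 150
    background_target_count: int = 50
    source_detection_prob: float = 0.9
    seed_ge7_prob: float = 0.9
    utr3_prob: float = 0.95
    false_edge_rate: float = 0.02  # expected false pairs per source / #true pairs
    validated_fraction: float = 0.05
    hub_target_disease_prob: float = 0.8
    n_individuals: int = 200
    call_rate: float = 0.02
    n_tfs: int = 15

    def __post_init__(self) -> None:
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if not (0 < self.source_detection_prob <= 1):
            raise ValueError("source_detection_prob must be in (0, 1]")
        if not (0 < self.disease_gene_fraction < 1):
            raise ValueError("disease_gene_fraction must be in (0, 1)")
        if self.false_edge_rate < 0 or not (0 <= self.call_rate < 1):
            raise ValueError("invalid rate parameter")
        if self.chrom_lengths is None:
            top, bottom = 250_000_000, 50_000_000
            step = (top - bottom) / max(self.n_chrom - 1, 1)
            self.chrom_lengths = [int(top - i * step) for i in range(self.n_chrom)]
        if len(self.chrom_lengths) != self.n_chrom:
            raise ValueError("chrom_lengths length must equal n_chrom")
        if self.mirna_length_bp >= min(self.chrom_lengths):
            raise ValueError("miRNA longer than the shortest chromosome")

    @classmethod
    def paperlike(cls, seed: int = 0) -> "SimulationConfig":
        """The default conditions (catalog-scale study); alias of the defaults."""
        return cls(seed=seed)


@dataclass
class SimulatedBundle:
    """In-memory view of one simulated input set."""

    config: SimulationConfig
    genome: GenomeBuild
    cnvs: list[CnvRecord]
    mirnas: list[MirnaGene]
    genes: list[str]
    gene_intervals: dict[str, GenomicInterval]
    predictions: list[PredictionRow]
    validated: list[PredictionRow]
    true_pairs: set[tuple[str, str]]
    planted_hubs: list[str]
    disease_genes: GeneSet
    calls: list[IndividualCnvCall]
    regulons: list[TfRegulon]
    mirna_tf_rows: list[PredictionRow]


def _draw_interval(rng: np.random.Generator, chrom: str, chrom_len: int,
                   lo: int, hi: int) -> GenomicInterval:
    length = int(rng.integers(lo, min(hi, chrom_len - 1) + 1))
    start = int(rng.integers(0, chrom_len - length))
    return GenomicInterval(chrom, start, start + length)


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Generate the full input bundle in memory (deterministic under the seed)."""
    chroms = [f"chr{i + 1}" for i in range(config.n_chrom)]
    genome = GenomeBuild(dict(zip(chroms, config.chrom_lengths)))

    # --- CNV loci: placement rate proportional to length x enrichment multiplier
    rng = _substream(config.seed, "cnvs")
    weights = np.array(
        [genome.length_of(c) * config.enriched_chroms.get(c, 1.0) for c in chroms], dtype=float
    )
    weights /= weights.sum()
    classes = list(config.class_probs)
    class_p = np.array([config.class_probs[c] for c in classes])
    cnvs = []
    lo, hi = config.cnv_length_range
    for i in range(config.n_cnvs):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        interval = _draw_interval(rng, chrom, genome.length_of(chrom), lo, hi)
        cls = classes[int(rng.choice(len(classes), p=class_p))]
        study_count = config.study_count_min - 1 + int(rng.geometric(config.study_count_geom_p))
        cnvs.append(CnvRecord(f"L{i + 1:04d}", interval, cls, study_count))

    # --- miRNA genes: uniform placement, planted hubs are the first ids
    rng = _substream(config.seed, "mirnas")
    len_weights = np.array([genome.length_of(c) for c in chroms], dtype=float)
    len_weights /= len_weights.sum()
    mirnas = []
    for j in range(config.n_mirnas):
        chrom = chroms[int(rng.choice(len(chroms), p=len_weights))]
        start = int(rng.integers(0, genome.length_of(chrom) - config.mirna_length_bp))
        mirnas.append(
            MirnaGene(
                f"mir-{j + 1:04d}",
                GenomicInterval(chrom, start, start + config.mirna_length_bp),
            )
        )
    planted_hubs = [m.mirna_id for m in mirnas[: config.n_planted_hubs]]

    # --- gene universe (synthetic symbols + the biogenesis machinery names)
    from .dosage_loops import MACHINERY_GENES

    machinery = sorted(MACHINERY_GENES.symbols)
    n_plain = max(config.n_genes - len(machinery), 0)
    genes = [f"G{i + 1:04d}" for i in range(n_plain)] + machinery
    rng = _substream(config.seed, "genes")
    gene_intervals = {}
    for gene in genes:
        chrom = chroms[int(rng.choice(len(chroms), p=len_weights))]
        start = int(rng.integers(0, max(genome.length_of(chrom) - config.gene_length_bp, 1)))
        gene_intervals[gene] = GenomicInterval(chrom, start, start + config.gene_length_bp)

    # --- true regulatory pairs, per-source detection, false edges, validation
    rng = _substream(config.seed, "targets")
    true_pairs: set[tuple[str, str]] = set()
    gene_arr = np.array(genes)
    for mirna in mirnas:
        k = config.hub_target_count if mirna.mirna_id in planted_hubs else config.background_target_count
        k = min(k, len(genes))
        for gene in rng.choice(gene_arr, size=k, replace=False):
            true_pairs.add((mirna.mirna_id, str(gene)))

    rng = _substream(config.seed, "predictions")
    predictions: list[PredictionRow] = []
    ordered_pairs = sorted(true_pairs)
    for source in SOURCES:
        detected = rng.random(len(ordered_pairs)) < config.source_detection_prob
        seed_hi = rng.random(len(ordered_pairs)) < config.seed_ge7_prob
        utr3 = rng.random(len(ordered_pairs)) < config.utr3_prob
        for idx, (mirna, gene) in enumerate(ordered_pairs):
            if not detected[idx]:
                continue
            seed_len = int(rng.integers(7, 9)) if seed_hi[idx] else int(rng.integers(4, 7))
            region = Region.UTR3 if utr3[idx] else Region(["UTR5", "CDS"][int(rng.integers(0, 2))])
            predictions.append(PredictionRow(mirna, gene, source, seed_len, region))
        n_false = int(rng.poisson(config.false_edge_rate * len(ordered_pairs)))
        for _ in range(n_false):
            mirna = mirnas[int(rng.integers(0, len(mirnas)))].mirna_id
            gene = genes[int(rng.integers(0, len(genes)))]
            if (mirna, gene) in true_pairs:
                continue
            seed_len = int(rng.integers(7, 9))
            predictions.append(PredictionRow(mirna, gene, source, seed_len, Region.UTR3))

    rng = _substream(config.seed, "validated")
    validated = [
        PredictionRow(m, g, validated=True)
        for (m, g) in ordered_pairs
        if rng.random() < config.validated_fraction
    ]

    # --- disease gene list: random fraction, hub targets favoured
    rng = _substream(config.seed, "disease")
    disease = {g for g in genes if rng.random() < config.disease_gene_fraction}
    hub_targets = {g for (m, g) in ordered_pairs if m in set(planted_hubs)}
    for gene in sorted(hub_targets):
        if rng.random() < config.hub_target_disease_prob:
            disease.add(gene)
    disease_genes = GeneSet("synthetic_disease_genes", disease)

    # --- individual-level calls for CNV-resident miRNAs and genes
    rng = _substream(config.seed, "calls")
    gene_loci = [MirnaGene(g, iv) for g, iv in gene_intervals.items()]
    mirna_hits = overlap_mirnas(cnvs, mirnas, OverlapPolicy.FULL_CONTAINMENT)
    gene_hits = overlap_mirnas(cnvs, gene_loci, OverlapPolicy.FULL_CONTAINMENT)
    cls_of = {c.locus_id: c.variation_class for c in cnvs}
    calls: list[IndividualCnvCall] = []

    def _emit(hits: dict[str, set[str]], kind: ElementKind) -> None:
        element_loci: dict[str, list[str]] = {}
        for locus, members in hits.items():
            for member in members:
                element_loci.setdefault(member, []).append(locus)
        for element in sorted(element_loci):
            locus = sorted(element_loci[element])[0]
            n_carriers = int(rng.binomial(config.n_individuals, config.call_rate))
            if n_carriers == 0:
                continue
            carriers = rng.choice(config.n_individuals, size=n_carriers, replace=False)
            cls = cls_of[locus]
            for ind in sorted(int(i) for i in carriers):
                if cls is VariationClass.DELETION:
                    state = CallState.DELETED
                elif cls is VariationClass.DUPLICATION:
                    state = CallState.DUPLICATED
                else:
                    state = CallState.DELETED if rng.random() < 0.5 else CallState.DUPLICATED
                calls.append(
                    IndividualCnvCall(f"ind{ind + 1:04d}", "synthetic_study", element, kind, state)
                )

    _emit(mirna_hits, ElementKind.MIRNA)
    _emit(gene_hits, ElementKind.GENE)

    # --- TF regulons over disease genes, plus miRNA -> TF interactions
    rng = _substream(config.seed, "tfs")
    disease_sorted = sorted(disease)
    regulons = []
    mirna_tf_rows = []
    for t in range(config.n_tfs):
        tf_id = f"TF{t + 1:02d}"
        size = int(rng.integers(10, min(61, max(11, len(disease_sorted)))))
        members = rng.choice(disease_sorted, size=min(size, len(disease_sorted)), replace=False)
        regulons.append(TfRegulon(tf_id, {str(g) for g in members}))
        for mirna in mirnas:
            p = 0.3 if mirna.mirna_id in planted_hubs else 0.02
            if rng.random() < p:
                mirna_tf_rows.append(PredictionRow(mirna.mirna_id, tf_id, validated=True))

    return SimulatedBundle(
        config=config,
        genome=genome,
        cnvs=cnvs,
        mirnas=mirnas,
        genes=genes,
        gene_intervals=gene_intervals,
        predictions=predictions,
        validated=validated,
        true_pairs=true_pairs,
        planted_hubs=planted_hubs,
        disease_genes=disease_genes,
        calls=calls,
        regulons=regulons,
        mirna_tf_rows=mirna_tf_rows,
    )


def simulate_inputs(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated bundle as the flat-text files tables_io reads.

    Returns a name -> path mapping. Byte-identical for identical config+seed.
    """
    bundle = simulate_bundle(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _path(name: str, filename: str) -> Path:
        paths[name] = outdir / filename
        return paths[name]

    with _path("genome", "genome.tsv").open("w", encoding="utf-8") as fh:
        fh.write("chrom\tlength_bp\n")
        for chrom in bundle.genome.chroms:
            fh.write(f"{chrom}\t{bundle.genome.length_of(chrom)}\n")

    with _path("cnvs", "cnvs.tsv").open("w", encoding="utf-8") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tvariation_class\tstudy_count\n")
        for cnv in bundle.cnvs:
            fh.write(
                f"{cnv.locus_id}\t{cnv.interval.chrom}\t{cnv.interval.start}\t"
                f"{cnv.interval.end}\t{cnv.variation_class.value.lower()}\t{cnv.study_count}\n"
            )

    with _path("mirnas", "mirnas.bed").open("w", encoding="utf-8") as fh:
        for mir in bundle.mirnas:
            fh.write(f"{mir.interval.chrom}\t{mir.interval.start}\t{mir.interval.end}\t{mir.mirna_id}\n")

    pred_header = "mirna_id\tgene_symbol\tsource_id\tseed_match_len\tregion\tvalidated\n"
    for source in SOURCES:
        with _path(f"predictions_{source}", f"predictions_{source}.tsv").open("w", encoding="utf-8") as fh:
            fh.write(pred_header)
            for row in bundle.predictions:
                if row.source_id == source:
                    fh.write(
                        f"{row.mirna_id}\t{row.gene_symbol}\t{row.source_id}\t"
                        f"{row.seed_match_len}\t{row.region.value}\tfalse\n"
                    )

    with _path("validated", "validated.tsv").open("w", encoding="utf-8") as fh:
        fh.write(pred_header)
        for row in bundle.validated:
            fh.write(f"{row.mirna_id}\t{row.gene_symbol}\t\t\t\ttrue\n")

    with _path("mirna_tf", "mirna_tf.tsv").open("w", encoding="utf-8") as fh:
        fh.write(pred_header)
        for row in bundle.mirna_tf_rows:
            fh.write(f"{row.mirna_id}\t{row.gene_symbol}\t\t\t\ttrue\n")

    with _path("disease_genes", "disease_genes.txt").open("w", encoding="utf-8") as fh:
        for gene in sorted(bundle.disease_genes.symbols):
            fh.write(gene + "\n")

    with _path("calls", "individual_calls.tsv").open("w", encoding="utf-8") as fh:
        fh.write("individual_id\tstudy_ref\telement_id\telement_kind\tstate\n")
        for call in bundle.calls:
            fh.write(
                f"{call.individual_id}\t{call.study_ref}\t{call.element_id}\t"
                f"{call.element_kind.value}\t{call.state.value}\n"
            )

    with _path("regulons", "tf_regulons.tsv").open("w", encoding="utf-8") as fh:
        fh.write("tf_id\tgene_symbol\n")
        for regulon in bundle.regulons:
            for gene in sorted(regulon.regulated_genes):
                fh.write(f"{regulon.tf_id}\t{gene}\n")

    return paths


# --------------------------------------------------------------------------
# Deterministic fixtures
# --------------------------------------------------------------------------

@dataclass
class SmallFixture:
    """Hand-verified 3-chromosome micro-dataset exercising every stage."""

    genome: GenomeBuild
    cnvs: list[CnvRecord]
    mirnas: list[MirnaGene]
    predictions: list[PredictionRow]
    master_genes: GeneSet
    calls: list[IndividualCnvCall]
    regulons: list[TfRegulon]
    mirna_tf_rows: list[PredictionRow]


def fixture_small() -> SmallFixture:
    """Fixed 3-chromosome, 8-CNV, 6-miRNA, 12-gene dataset.

    Designed so that the study-count filter keeps 5 of 8 loci, the consensus
    network has 14 edges with the planted hub (mir-1, degree 6) ranked first,
    and the dosage partition has exclusive regions of sizes 2/1/1 and a triple
    intersection of 1.
    """
    genome = GenomeBuild({"chrA": 100_000, "chrB": 100_000, "chrC": 100_000})
    mk = lambda lid, chrom, s, e, cls, n: CnvRecord(lid, GenomicInterval(chrom, s, e), cls, n)
    cnvs = [
        mk("L1", "chrA", 0, 30_000, VariationClass.DELETION, 3),
        mk("L2", "chrA", 40_000, 70_000, VariationClass.DUPLICATION, 2),
        mk("L3", "chrB", 0, 30_000, VariationClass.BOTH, 6),
        mk("L4", "chrB", 40_000, 60_000, VariationClass.DELETION, 1),
        mk("L5", "chrB", 60_000, 90_000, VariationClass.DUPLICATION, 4),
        mk("L6", "chrC", 0, 20_000, VariationClass.BOTH, 5),
        mk("L7", "chrC", 30_000, 60_000, VariationClass.DELETION, 2),
        mk("L8", "chrC", 70_000, 90_000, VariationClass.DUPLICATION, 1),
    ]
    mir = lambda mid, chrom, s: MirnaGene(mid, GenomicInterval(chrom, s, s + 80))
    mirnas = [
        mir("mir-1", "chrA", 1_000),   # in L1 -> DELETED
        mir("mir-2", "chrA", 45_000),  # in L2 -> DUPLICATED
        mir("mir-3", "chrB", 5_000),   # in L3 -> DELETED_DUPLICATED
        mir("mir-4", "chrB", 65_000),  # in L5 -> DUPLICATED
        mir("mir-5", "chrC", 35_000),  # in L7 -> DELETED
        mir("mir-6", "chrC", 50_000),  # in L7 -> DELETED (no consensus targets)
    ]
    consensus_pairs = {
        "mir-1": ["G01", "G03", "G04", "G05", "G06", "G10"],
        "mir-2": ["G01", "G09", "G10"],
        "mir-3": ["G01", "G05", "G08"],
        "mir-4": ["G06"],
    }
    predictions = [
        PredictionRow(mirna, gene, source, 7, Region.UTR3)
        for mirna, targets in consensus_pairs.items()
        for gene in targets
        for source in SOURCES
    ]
    # mir-6's only candidate target is concordant in 3 of 4 sources: no edge
    predictions += [PredictionRow("mir-6", "G11", s, 7, Region.UTR3) for s in SOURCES[:3]]
    predictions.append(PredictionRow("mir-5", "G01", validated=True))  # validated-only edge

    master_genes = GeneSet("fixture_master", {f"G{i:02d}" for i in range(1, 13)})
    calls = [
        IndividualCnvCall("ind1", "S1", "mir-1", ElementKind.MIRNA, CallState.DELETED),
        IndividualCnvCall("ind2", "S1", "G01", ElementKind.GENE, CallState.DUPLICATED),
        IndividualCnvCall("ind3", "S2", "mir-2", ElementKind.MIRNA, CallState.DUPLICATED),
        IndividualCnvCall("ind4", "S2", "G09", ElementKind.GENE, CallState.DELETED),
    ]
    regulons = [TfRegulon("TF1", {"G01", "G03"}), TfRegulon("TF2", {"G05", "G08"})]
    mirna_tf_rows = [PredictionRow("mir-1", "TF1", validated=True)]
    return SmallFixture(genome, cnvs, mirnas, predictions, master_genes, calls, regulons, mirna_tf_rows)


def fixture_locus_catalog() -> tuple[list[CnvRecord], list[MirnaGene]]:
    """Synthetic locus catalog reproducing published marginal counts.

    1145 CNV records of which exactly 378 pass the study-count filter
    (thresholds 2/6); among the kept loci, 41 harbor miRNA genes — 11
    deletion-only, 9 duplication-only and 21 combination loci — carrying 71
    miRNAs in total. Coordinates are synthetic (one long chromosome); a few
    extra miRNAs sit inside sub-threshold loci and must disappear after
    selection.
    """
    cnvs: list[CnvRecord] = []
    mirnas: list[MirnaGene] = []
    chrom = "chr1"
    spacing, width = 10_000, 5_000

    def add_locus(cls: VariationClass, sc: int, n_mirnas_here: int) -> None:
        i = len(cnvs)
        start = i * spacing
        cnvs.append(CnvRecord(f"SL{i + 1:04d}", GenomicInterval(chrom, start, start + width), cls, sc))
        for k in range(n_mirnas_here):
            pos = start + 500 + 200 * k
            mirnas.append(MirnaGene(f"smir-{len(mirnas) + 1:03d}", GenomicInterval(chrom, pos, pos + 80)))

    # 41 miRNA-bearing kept loci holding 71 miRNAs: the 30 extra copies go to
    # the first 30 loci (2 each), the remaining 11 get 1 each.
    bearing = [(VariationClass.DELETION, 2)] * 11 + [(VariationClass.DUPLICATION, 2)] * 9 \
        + [(VariationClass.BOTH, 6)] * 21
    for idx, (cls, sc) in enumerate(bearing):
        add_locus(cls, sc, 2 if idx < 30 else 1)
    # 337 kept loci without miRNAs -> 378 kept in total
    for _ in range(337):
        add_locus(VariationClass.DELETION, 3, 0)
    # 767 sub-threshold loci -> 1145 in total; 3 of them contain decoy miRNAs
    for j in range(767):
        cls, sc = (VariationClass.BOTH, 5) if j < 267 else (VariationClass.DELETION, 1)
        add_locus(cls, sc, 1 if j < 3 else 0)
    assert len(cnvs) == 1145
    return cnvs, mirnas


def fixture_dosage_sets() -> dict[CnvState, set[str]]:
    """Synthetic per-state target sets with the published region cardinalities.

    Exclusive regions of 35 (deleted-only), 32 (duplicated-only) and 94
    (deleted-duplicated-only) genes, a triple intersection of 44, and pairwise
    intersections of 40/40/41 — 326 targeted genes in total.
    """
    pool = iter(f"T{i + 1:04d}" for i in range(326))
    take = lambda n: {next(pool) for _ in range(n)}
    del_only, dup_only, dd_only, triple = take(35), take(32), take(94), take(44)
    del_dup, del_dd, dup_dd = take(40), take(40), take(41)
    return {
        CnvState.DELETED: del_only | del_dup | del_dd | triple,
        CnvState.DUPLICATED: dup_only | del_dup | dup_dd | triple,
        CnvState.DELETED_DUPLICATED: dd_only | del_dd | dup_dd | triple,
    }
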