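"""Domain types and readers/writers for every table and graph format the pipeline touches.

All genomic coordinates are held internally as 0-based half-open intervals
(BED convention). Tabular inputs declare their coordinate convention through a
:class:`TableDialect` and are converted on read. Gene symbols are upper-cased
and whitespace-trimmed before any set operation, since merged symbol lists from
different databases disagree on case.
"""
from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "RowValidationError",
    "VariationClass",
    "CnvState",
    "CallState",
    "ElementKind",
    "Region",
    "GenomeBuild",
    "GenomicInterval",
    "CnvRecord",
    "MirnaGene",
    "PredictionRow",
    "GeneSet",
    "IndividualCnvCall",
    "TfRegulon",
    "TableDialect",
    "normalize_symbol",
    "read_genome_table",
    "read_cnv_table",
    "read_bed",
    "read_predictions",
    "read_gene_set",
    "read_individual_calls",
    "read_tf_regulons",
    "write_network",
    "read_network",
]


class FormatError(ValueError):
    """A file is structurally unusable (e.g. a required column is missing)."""


class RowValidationError(ValueError):
    """A single row violates a type invariant; carries the 1-based line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


class VariationClass(str, enum.Enum):
    """Copy-number class of a CNV locus across the studies reporting it."""

    DELETION = "DELETION"
    DUPLICATION = "DUPLICATION"
    BOTH = "BOTH"


class CnvState(str, enum.Enum):
    """Derived copy-number state of a miRNA gene (union over its host loci)."""

    DELETED = "DELETED"
    DUPLICATED = "DUPLICATED"
    DELETED_DUPLICATED = "DELETED_DUPLICATED"


class CallState(str, enum.Enum):
    """State of one CNV call in one individual."""

    DELETED = "DELETED"
    DUPLICATED = "DUPLICATED"


class ElementKind(str, enum.Enum):
    MIRNA = "MIRNA"
    GENE = "GENE"


class Region(str, enum.Enum):
    """mRNA region of a predicted miRNA binding site."""

    UTR3 = "UTR3"
    UTR5 = "UTR5"
    CDS = "CDS"


def normalize_symbol(symbol: str) -> str:
    """Case/whitespace normalization applied to every gene symbol on read."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the intersection is at least 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeBuild:
    """Ordered chromosome name -> length (bp) table."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length {length}")

    @property
    def chroms(self) -> list[str]:
        return list(self.lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    def length_of(self, chrom: str) -> int:
        return self.lengths[chrom]


@dataclass(frozen=True)
class CnvRecord:
    """One CNV locus with coordinates, class and supporting-study count."""

    locus_id: str
    interval: GenomicInterval
    variation_class: VariationClass
    study_count: int

    def __post_init__(self) -> None:
        if self.study_count < 1:
            raise ValueError(f"{self.locus_id}: study_count must be >= 1")


@dataclass(frozen=True)
class MirnaGene:
    """A miRNA gene's coordinates; isomiR/star status is a naming heuristic."""

    mirna_id: str
    interval: GenomicInterval
    is_star_or_isomir: bool = False


@dataclass(frozen=True)
class PredictionRow:
    """One miRNA->gene row from a prediction source or a validated-interaction table."""

    mirna_id: str
    gene_symbol: str
    source_id: str | None = None
    seed_match_len: int | None = None
    region: Region | None = None
    validated: bool = False

    def __post_init__(self) -> None:
        if not self.validated:
            if self.source_id is None or self.seed_match_len is None or self.region is None:
                raise ValueError(
                    f"predicted row ({self.mirna_id}, {self.gene_symbol}) must set "
                    "source_id, seed_match_len and region"
                )
        if self.seed_match_len is not None and self.seed_match_len < 0:
            raise ValueError("seed_match_len must be non-negative")


@dataclass
class GeneSet:
    """A named set of upper-cased gene symbols."""

    name: str
    symbols: set[str]

    def __post_init__(self) -> None:
        self.symbols = {normalize_symbol(s) for s in self.symbols}

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class IndividualCnvCall:
    """One deletion/duplication call of a miRNA or gene in one individual."""

    individual_id: str
    study_ref: str
    element_id: str
    element_kind: ElementKind
    state: CallState


@dataclass
class TfRegulon:
    """A transcription factor and the genes under its control."""

    tf_id: str
    regulated_genes: set[str]

    def __post_init__(self) -> None:
        if not self.regulated_genes:
            raise ValueError(f"regulon of {self.tf_id} is empty")
        self.regulated_genes = {normalize_symbol(g) for g in self.regulated_genes}


# --------------------------------------------------------------------------
# Tabular readers
# --------------------------------------------------------------------------

#: recognised coordinate conventions for tabular inputs
COORD_CONVENTIONS = ("0-based-half-open", "1-based-closed")


@dataclass
class TableDialect:
    """Column aliases and coordinate convention of a tabular input.

    ``columns`` maps canonical column names to the header names used by the
    file; canonical names missing from the mapping are looked up verbatim.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    coords: str = "1-based-closed"
    delimiter: str | None = None  # None -> sniff tab vs comma from the header

    def __post_init__(self) -> None:
        if self.coords not in COORD_CONVENTIONS:
            raise ValueError(
                f"unknown coordinate convention {self.coords!r}; "
                f"expected one of {COORD_CONVENTIONS}"
            )

    def col(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    def to_internal(self, start: int, end: int) -> tuple[int, int]:
        """Convert declared-convention coordinates to 0-based half-open."""
        if self.coords == "1-based-closed":
            return start - 1, end
        return start, end

    def from_internal(self, start: int, end: int) -> tuple[int, int]:
        if self.coords == "1-based-closed":
            return start + 1, end
        return start, end


def _open_reader(path: str | Path, dialect: TableDialect) -> tuple[csv.DictReader, object]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    handle = path.open(newline="", encoding="utf-8")
    first = handle.readline()
    handle.seek(0)
    delim = dialect.delimiter or ("\t" if "\t" in first else ",")
    return csv.DictReader(handle, delimiter=delim), handle


def _require_columns(reader: csv.DictReader, names: Sequence[str], path) -> None:
    header = reader.fieldnames or []
    missing = [n for n in names if n not in header]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


_CLASS_ALIASES = {
    "deletion": VariationClass.DELETION,
    "del": VariationClass.DELETION,
    "loss": VariationClass.DELETION,
    "duplication": VariationClass.DUPLICATION,
    "dup": VariationClass.DUPLICATION,
    "gain": VariationClass.DUPLICATION,
    "both": VariationClass.BOTH,
    "deletion-duplication": VariationClass.BOTH,
    "del-dup": VariationClass.BOTH,
}


def read_cnv_table(path: str | Path, dialect: TableDialect | None = None) -> list[CnvRecord]:
    """Read a CNV locus table (locus id, chrom, start, end, class, study count).

    The dialect's declared coordinate convention (default 1-based closed, the
    genome-browser style of most published locus tables) is converted to the
    internal 0-based half-open convention.
    """
    dialect = dialect or TableDialect()
    cols = [dialect.col(c) for c in ("locus_id", "chrom", "start", "end", "variation_class", "study_count")]
    reader, handle = _open_reader(path, dialect)
    with handle:
        _require_columns(reader, cols, path)
        records: list[CnvRecord] = []
        for line_no, row in enumerate(reader, start=2):
            c_id, c_chr, c_s, c_e, c_cls, c_n = (row[c] for c in cols)
            try:
                start, end = int(c_s), int(c_e)
            except ValueError:
                raise RowValidationError(f"non-integer coordinates ({c_s!r}, {c_e!r})", line_no)
            start, end = dialect.to_internal(start, end)
            if start >= end:
                raise RowValidationError(
                    f"locus {c_id}: start >= end after conversion ({start} >= {end})", line_no
                )
            cls = _CLASS_ALIASES.get(c_cls.strip().lower())
            if cls is None:
                raise RowValidationError(f"unknown variation class {c_cls!r}", line_no)
            try:
                study_count = int(c_n)
            except ValueError:
                raise RowValidationError(f"non-integer study count {c_n!r}", line_no)
            try:
                records.append(
                    CnvRecord(c_id.strip(), GenomicInterval(c_chr.strip(), start, end), cls, study_count)
                )
            except ValueError as exc:
                raise RowValidationError(str(exc), line_no)
    return records


def read_genome_table(path: str | Path, dialect: TableDialect | None = None) -> GenomeBuild:
    """Read a chromosome-length table with columns ``chrom`` and ``length_bp``."""
    dialect = dialect or TableDialect()
    cols = [dialect.col(c) for c in ("chrom", "length_bp")]
    reader, handle = _open_reader(path, dialect)
    lengths: dict[str, int] = {}
    with handle:
        _require_columns(reader, cols, path)
        for line_no, row in enumerate(reader, start=2):
            chrom = row[cols[0]].strip()
            if chrom in lengths:
                raise RowValidationError(f"duplicate chromosome {chrom}", line_no)
            try:
                lengths[chrom] = int(row[cols[1]])
            except ValueError:
                raise RowValidationError(f"non-integer length {row[cols[1]]!r}", line_no)
    return GenomeBuild(lengths)


def is_star_or_isomir_name(mirna_id: str) -> bool:
    """Naming heuristic for star/arm-variant miRNAs; informational only."""
    return mirna_id.endswith("*") or "-3p" in mirna_id or "-5p" in mirna_id


def read_bed(path: str | Path) -> list[MirnaGene]:
    """Read miRNA gene coordinates from a BED3/BED4+ file (0-based half-open)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    records: list[MirnaGene] = []
    with path.open(encoding="utf-8") as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise RowValidationError(f"BED line has {len(fields)} fields, need >= 3", line_no)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise RowValidationError(f"non-integer BED coordinates {fields[1:3]}", line_no)
            name = fields[3] if len(fields) >= 4 and fields[3] else f"mir_{line_no}"
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise RowValidationError(str(exc), line_no)
            records.append(MirnaGene(name, interval, is_star_or_isomir_name(name)))
    return records


_REGION_ALIASES = {
    "utr3": Region.UTR3,
    "3utr": Region.UTR3,
    "3'utr": Region.UTR3,
    "utr5": Region.UTR5,
    "5utr": Region.UTR5,
    "5'utr": Region.UTR5,
    "cds": Region.CDS,
}

_TRUE_STRINGS = {"1", "true", "yes", "y", "t"}


def read_predictions(paths: str | Path | Iterable[str | Path],
                     dialect: TableDialect | None = None) -> list[PredictionRow]:
    """Read one or more miRNA->gene prediction / validated-interaction tables.

    Columns: mirna_id, gene_symbol, and either validated=true or the triple
    (source_id, seed_match_len, region). Duplicate (mirna, gene, source) rows
    are collapsed to one with a logged count; gene symbols are normalized.
    """
    dialect = dialect or TableDialect()
    if isinstance(paths, (str, Path)):
        paths = [paths]
    seen: dict[tuple, PredictionRow] = {}
    n_dupes = 0
    for path in paths:
        reader, handle = _open_reader(path, dialect)
        with handle:
            base = [dialect.col(c) for c in ("mirna_id", "gene_symbol")]
            _require_columns(reader, base, path)
            header = reader.fieldnames or []
            for line_no, row in enumerate(reader, start=2):
                mirna = row[base[0]].strip()
                gene = normalize_symbol(row[base[1]])
                val_col = dialect.col("validated")
                validated = (
                    val_col in header
                    and (row.get(val_col) or "").strip().lower() in _TRUE_STRINGS
                )
                if validated:
                    rec = PredictionRow(mirna, gene, validated=True)
                else:
                    source = (row.get(dialect.col("source_id")) or "").strip()
                    seed = (row.get(dialect.col("seed_match_len")) or "").strip()
                    region_s = (row.get(dialect.col("region")) or "").strip()
                    if not source or not seed or not region_s:
                        raise RowValidationError(
                            f"predicted row ({mirna}, {gene}) missing source/seed/region", line_no
                        )
                    region = _REGION_ALIASES.get(region_s.lower())
                    if region is None:
                        raise RowValidationError(f"unknown region {region_s!r}", line_no)
                    try:
                        seed_len = int(seed)
                    except ValueError:
                        raise RowValidationError(f"non-integer seed length {seed!r}", line_no)
                    try:
                        rec = PredictionRow(mirna, gene, source.lower(), seed_len, region)
                    except ValueError as exc:
                        raise RowValidationError(str(exc), line_no)
                key = (rec.mirna_id, rec.gene_symbol, rec.source_id, rec.validated,
                       rec.seed_match_len, rec.region)
                if key in seen:
                    n_dupes += 1
                else:
                    seen[key] = rec
    if n_dupes:
        log.info("read_predictions: collapsed %d duplicate row(s)", n_dupes)
    return list(seen.values())


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a plain-text gene list, one symbol per line; symbols normalized."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    symbols = set()
    with path.open(encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(normalize_symbol(line))
    return GeneSet(name or path.stem, symbols)


def read_individual_calls(path: str | Path, dialect: TableDialect | None = None) -> list[IndividualCnvCall]:
    """Read individual-level CNV calls (individual, study, element, kind, state)."""
    dialect = dialect or TableDialect()
    cols = [dialect.col(c) for c in ("individual_id", "study_ref", "element_id", "element_kind", "state")]
    reader, handle = _open_reader(path, dialect)
    calls: list[IndividualCnvCall] = []
    with handle:
        _require_columns(reader, cols, path)
        for line_no, row in enumerate(reader, start=2):
            kind_s = row[cols[3]].strip().upper()
            state_s = row[cols[4]].strip().upper()
            try:
                kind = ElementKind(kind_s)
            except ValueError:
                raise RowValidationError(f"unknown element kind {kind_s!r}", line_no)
            try:
                state = CallState(state_s)
            except ValueError:
                raise RowValidationError(f"unknown call state {state_s!r}", line_no)
            element = row[cols[2]].strip()
            if kind is ElementKind.GENE:
                element = normalize_symbol(element)
            calls.append(IndividualCnvCall(row[cols[0]].strip(), row[cols[1]].strip(), element, kind, state))
    return calls


def read_tf_regulons(path: str | Path, dialect: TableDialect | None = None) -> list[TfRegulon]:
    """Read TF->gene regulation rows (tf_id, gene_symbol) into regulons."""
    dialect = dialect or TableDialect()
    cols = [dialect.col(c) for c in ("tf_id", "gene_symbol")]
    reader, handle = _open_reader(path, dialect)
    regulons: dict[str, set[str]] = {}
    with handle:
        _require_columns(reader, cols, path)
        for row in reader:
            regulons.setdefault(row[cols[0]].strip(), set()).add(normalize_symbol(row[cols[1]]))
    return [TfRegulon(tf, genes) for tf, genes in regulons.items()]


# --------------------------------------------------------------------------
# Network I/O
# --------------------------------------------------------------------------

NETWORK_FORMATS = ("graphml", "sif", "edge_tsv")


def write_network(network, path: str | Path, format: str = "graphml",
                  allow_empty: bool = False) -> None:
    """Write a bipartite miRNA-target network to GraphML, SIF or a TSV edge list.

    GraphML and edge_tsv round-trip exactly (node set, edge set, evidence and
    source attributes); SIF is a lossy export for viewers.
    """
    import networkx as nx

    from .regnet import BipartiteNetwork  # deferred: regnet imports this module

    assert isinstance(network, BipartiteNetwork)
    if format not in NETWORK_FORMATS:
        raise ValueError(f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}")
    if not allow_empty and not network.mirna_nodes and not network.gene_nodes:
        raise ValueError("refusing to write an empty network (pass allow_empty=True to override)")
    path = Path(path)
    if format == "graphml":
        graph = network.to_networkx()
        nx.write_graphml(graph, path)
        return
    with path.open("w", encoding="utf-8") as handle:
        if format == "sif":
            for edge in sorted(network.edges.values(), key=lambda e: (e.mirna_id, e.gene_symbol)):
                handle.write(f"{edge.mirna_id} targets {edge.gene_symbol}\n")
        else:  # edge_tsv
            handle.write(f"# mirna_nodes: {','.join(sorted(network.mirna_nodes))}\n")
            handle.write(f"# gene_nodes: {','.join(sorted(network.gene_nodes))}\n")
            handle.write("mirna_id\tgene_symbol\tevidence\tsupporting_sources\n")
            for edge in sorted(network.edges.values(), key=lambda e: (e.mirna_id, e.gene_symbol)):
                handle.write(
                    f"{edge.mirna_id}\t{edge.gene_symbol}\t{edge.evidence.value}\t"
                    f"{','.join(sorted(edge.supporting_sources))}\n"
                )


def read_network(path: str | Path, format: str = "graphml"):
    """Read a network written by :func:`write_network` (graphml or edge_tsv)."""
    import networkx as nx

    from .regnet import BipartiteNetwork, Evidence, InteractionEdge

    if format not in ("graphml", "edge_tsv"):
        raise ValueError(f"cannot read network format {format!r}; use graphml or edge_tsv")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    mirnas: set[str] = set()
    genes: set[str] = set()
    edges: dict[tuple[str, str], "InteractionEdge"] = {}
    if format == "graphml":
        graph = nx.read_graphml(path)
        for node, data in graph.nodes(data=True):
            (mirnas if data.get("kind") == "mirna" else genes).add(node)
        for u, v, data in graph.edges(data=True):
            mirna, gene = (u, v) if u in mirnas else (v, u)
            sources = frozenset(s for s in data.get("sources", "").split(",") if s)
            edges[(mirna, gene)] = InteractionEdge(
                mirna, gene, Evidence(data.get("evidence", "PREDICTED")), sources
            )
    else:
        with path.open(encoding="utf-8") as handle:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("# mirna_nodes:"):
                    mirnas = {s for s in line.split(":", 1)[1].strip().split(",") if s}
                elif line.startswith("# gene_nodes:"):
                    genes = {s for s in line.split(":", 1)[1].strip().split(",") if s}
                elif line and not line.startswith(("#", "mirna_id\t")):
                    mirna, gene, evidence, sources = (line.split("\t") + [""])[:4]
                    edges[(mirna, gene)] = InteractionEdge(
                        mirna, gene, Evidence(evidence),
                        frozenset(s for s in sources.split(",") if s),
                    )
    return BipartiteNetwork(mirnas, genes, edges)
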