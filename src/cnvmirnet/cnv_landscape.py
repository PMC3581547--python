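"""Chromosome-level normalized CNV density and the study-count selection filter.

The density of chromosome *c* is the number of CNV loci on *c* divided by its
length; the normalized density divides by the mean raw density over all
chromosomes of the genome build, so the normalized values average to exactly 1.
A chromosome is flagged *enriched* when its normalized density exceeds the mean
(which is 1 by construction) by more than one sample standard deviation of the
normalized densities — chromosomes within one SD of the mean are treated as
unremarkable. The normalization is reconstructed from the descriptive account
of the density correction (the original formula is only shown graphically) and
is documented as a reconstruction in the methods note.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables_io import CnvRecord, GenomeBuild, VariationClass

__all__ = ["DensityResult", "compute_cnv_density", "select_consistent_cnvs"]


@dataclass(frozen=True)
class DensityResult:
    chrom: str
    cnv_count: int
    length_bp: int
    raw_density: float        # CNVs per bp
    normalized_density: float  # raw density / mean raw density, dimensionless
    enriched: bool


def compute_cnv_density(cnvs: list[CnvRecord], genome: GenomeBuild) -> list[DensityResult]:
    """Per-chromosome normalized CNV density with enrichment flags.

    Chromosomes with zero CNVs are retained (they lower the mean). The sample
    standard deviation (n-1 denominator) of the normalized densities defines
    the enrichment band: enriched iff normalized density > 1 + SD.
    """
    if len(genome) < 2:
        raise ValueError("genome must have >= 2 chromosomes (SD of densities undefined)")
    counts = {chrom: 0 for chrom in genome.chroms}
    orphans = [c.locus_id for c in cnvs if c.interval.chrom not in counts]
    if orphans:
        raise ValueError(
            "CNV loci on chromosomes absent from the genome build: " + ", ".join(orphans)
        )
    for cnv in cnvs:
        counts[cnv.interval.chrom] += 1
    raw = np.array([counts[c] / genome.length_of(c) for c in genome.chroms], dtype=float)
    mean_raw = raw.mean()
    if mean_raw == 0:
        normalized = np.zeros_like(raw)
        sd = 0.0
    else:
        normalized = raw / mean_raw
        sd = float(normalized.std(ddof=1))
    return [
        DensityResult(
            chrom=chrom,
            cnv_count=counts[chrom],
            length_bp=genome.length_of(chrom),
            raw_density=float(raw[i]),
            normalized_density=float(normalized[i]),
            enriched=bool(normalized[i] > 1.0 + sd),
        )
        for i, chrom in enumerate(genome.chroms)
    ]


def select_consistent_cnvs(cnvs: list[CnvRecord],
                           min_studies_single: int = 2,
                           min_studies_both: int = 6) -> list[CnvRecord]:
    """Keep CNV loci consistently reported across independent studies.

    A locus that is only deleted or only duplicated must be supported by at
    least ``min_studies_single`` studies (default 2); a locus reported with
    both deletion and duplication must be supported by at least
    ``min_studies_both`` studies (default 6, i.e. "more than 5"). Input order
    is preserved and the filter is idempotent.
    """
    if min_studies_single < 1 or min_studies_both < 1:
        raise ValueError("study-count thresholds must be >= 1")
    kept = []
    for cnv in cnvs:
        threshold = (
            min_studies_both if cnv.variation_class is VariationClass.BOTH
            else min_studies_single
        )
        if cnv.study_count >= threshold:
            kept.append(cnv)
    return kept
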