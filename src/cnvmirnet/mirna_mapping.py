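"""Map miRNA genes into selected CNV loci and derive each miRNA's CNV state.

Overlap uses a sorted sweep over interval endpoints (O((n+m) log(n+m)) plus
output size). The default assignment policy is *full containment* — a miRNA is
assigned to a CNV locus only when its hairpin lies entirely inside the locus,
since a partial overlap is not a clean copy-number change of the miRNA; the
``any_overlap`` policy (>= 1 bp intersection) is available as an alternative.

A miRNA's CNV state is the union over the classes of all loci containing it:
all-deletion loci -> DELETED, all-duplication -> DUPLICATED, and any mixture
(or any locus of class BOTH) -> DELETED_DUPLICATED.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

from .tables_io import CnvRecord, MirnaGene, CnvState, VariationClass

__all__ = ["OverlapPolicy", "CnvMirnaAssignment", "overlap_mirnas", "classify_mirna_state"]


class OverlapPolicy(str, enum.Enum):
    FULL_CONTAINMENT = "full_containment"
    ANY_OVERLAP = "any_overlap"


@dataclass(frozen=True)
class CnvMirnaAssignment:
    mirna_id: str
    locus_ids: frozenset[str]
    cnv_state: CnvState

    def __post_init__(self) -> None:
        if not self.locus_ids:
            raise ValueError(f"{self.mirna_id}: assignment with no contributing loci")


def overlap_mirnas(
    cnvs: list[CnvRecord],
    mirnas: list[MirnaGene],
    policy: OverlapPolicy | str = OverlapPolicy.FULL_CONTAINMENT,
) -> dict[str, set[str]]:
    """Assign miRNA genes to CNV loci; returns locus_id -> set of mirna_id.

    Loci with no miRNA map to the empty set (retained). Strand is ignored
    (CNVs are unstranded events). Intervals are half-open, so a miRNA abutting
    a locus boundary does not overlap it.
    """
    policy = OverlapPolicy(policy)
    result: dict[str, set[str]] = {c.locus_id: set() for c in cnvs}

    # Sweep events per chromosome: starts open an interval, ends close it.
    # When a miRNA starts, every active CNV has start <= miRNA start; when a
    # CNV starts, every active miRNA straddles the CNV start (pure overlap,
    # never containment of the miRNA). CNV starts are processed before miRNA
    # starts at the same coordinate so that containment at a shared left edge
    # is seen; ends are processed before starts at the same coordinate to
    # honour half-open abutment.
    END, CNV_START, MIR_START = 0, 1, 2
    events: list[tuple[str, int, int, int]] = []  # (chrom, pos, kind, index)
    for i, cnv in enumerate(cnvs):
        events.append((cnv.interval.chrom, cnv.interval.start, CNV_START, i))
        events.append((cnv.interval.chrom, cnv.interval.end, END, i))
    for j, mir in enumerate(mirnas):
        events.append((mir.interval.chrom, mir.interval.start, MIR_START, j))
        events.append((mir.interval.chrom, mir.interval.end, END, len(cnvs) + j))
    events.sort(key=lambda e: (e[0], e[1], e[2]))

    active_cnvs: dict[int, CnvRecord] = {}
    active_mirs: dict[int, MirnaGene] = {}
    prev_chrom = None
    for chrom, _pos, kind, idx in events:
        if chrom != prev_chrom:
            active_cnvs.clear()
            active_mirs.clear()
            prev_chrom = chrom
        if kind == END:
            active_cnvs.pop(idx, None)
            active_mirs.pop(idx - len(cnvs), None)
        elif kind == CNV_START:
            cnv = cnvs[idx]
            active_cnvs[idx] = cnv
            if policy is OverlapPolicy.ANY_OVERLAP:
                # miRNAs already open at the CNV start overlap it by >= 1 bp
                for mir in active_mirs.values():
                    result[cnv.locus_id].add(mir.mirna_id)
        else:  # MIR_START
            mir = mirnas[idx]
            active_mirs[idx] = mir
            for cnv in active_cnvs.values():
                if policy is OverlapPolicy.ANY_OVERLAP or cnv.interval.end >= mir.interval.end:
                    result[cnv.locus_id].add(mir.mirna_id)
    return result


def classify_mirna_state(
    assignments: dict[str, set[str]],
    cnvs: list[CnvRecord],
) -> list[CnvMirnaAssignment]:
    """Derive each assigned miRNA's CNV state from its host loci's classes.

    Results are sorted by miRNA id. The three states partition the assigned
    miRNAs: no miRNA is reported twice and every assigned miRNA is reported.
    """
    classes = {c.locus_id: c.variation_class for c in cnvs}
    unknown = sorted(set(assignments) - set(classes))
    if unknown:
        raise ValueError("assignments reference unknown locus id(s): " + ", ".join(unknown))
    per_mirna: dict[str, set[str]] = {}
    for locus_id, mirna_ids in assignments.items():
        for mirna_id in mirna_ids:
            per_mirna.setdefault(mirna_id, set()).add(locus_id)
    out = []
    for mirna_id in sorted(per_mirna):
        locus_ids = per_mirna[mirna_id]
        seen = {classes[l] for l in locus_ids}
        if seen == {VariationClass.DELETION}:
            state = CnvState.DELETED
        elif seen == {VariationClass.DUPLICATION}:
            state = CnvState.DUPLICATED
        else:
            state = CnvState.DELETED_DUPLICATED
        out.append(CnvMirnaAssignment(mirna_id, frozenset(locus_ids), state))
    return out
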