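"""Map miRNA genes into selected CNV loci and derive their copy-number states.

Uses the hand-verified micro-dataset that ships with the package. A miRNA
inside only deletion loci is DELETED, inside only duplication loci DUPLICATED,
and anything mixed (or inside a locus seen both deleted and duplicated across
individuals) is DELETED_DUPLICATED.
"""
from cnvmirnet.cnv_landscape import select_consistent_cnvs
from cnvmirnet.mirna_mapping import classify_mirna_state, overlap_mirnas
from cnvmirnet.synthgen import fixture_small

fx = fixture_small()
selected = select_consistent_cnvs(fx.cnvs)
print(f"{len(selected)} of {len(fx.cnvs)} CNV loci pass the consistency filter")

hits = overlap_mirnas(selected, fx.mirnas, policy="full_containment")
for locus, members in sorted(hits.items()):
    print(f"  {locus}: {sorted(members) if members else '-'}")

print()
print("miRNA   state                locus")
for a in classify_mirna_state(hits, selected):
    print(f"{a.mirna_id:7s} {a.cnv_state.value:20s} {','.join(sorted(a.locus_ids))}")
print()
print("mir-3 sits in a locus reported both deleted and duplicated, so its")
print("copy-number state (and its targets' dosage) can swing either way.")
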