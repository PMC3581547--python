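import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvmirnet.dosage_loops import (
    MACHINERY_GENES,
    DosageLabel,
    LoopMode,
    assemble_tf_loops,
    biogenesis_subnetwork,
    dosage_partition,
    find_inverse_pairs,
)
from cnvmirnet.tables_io import (
    CallState,
    CnvState,
    ElementKind,
    GeneSet,
    IndividualCnvCall,
    TfRegulon,
)
from conftest import predicted
from helpers_oracles import brute_inverse_pairs


def by_state(deleted=(), duplicated=(), deldup=()):
    return {
        CnvState.DELETED: set(deleted),
        CnvState.DUPLICATED: set(duplicated),
        CnvState.DELETED_DUPLICATED: set(deldup),
    }


class TestDosagePartition:
    def test_small_example(self):
        p = dosage_partition(by_state({"A", "B"}, {"B", "C"}, {"B"}))
        assert p.regions["deleted_only"] == {"A"}
        assert p.regions["duplicated_only"] == {"C"}
        assert p.regions["central"] == {"B"}
        assert p.labels["deleted_only"] is DosageLabel.INCREASE
        assert p.labels["duplicated_only"] is DosageLabel.DECREASE
        assert p.labels["deleted_duplicated_only"] is DosageLabel.FLUCTUATE
        assert p.labels["central"] is DosageLabel.CENTRAL
        assert p.labels["deleted_and_duplicated"] is DosageLabel.MIXED

    def test_all_equal_sets_everything_central(self):
        p = dosage_partition(by_state({"X", "Y"}, {"X", "Y"}, {"X", "Y"}))
        assert p.regions["central"] == {"X", "Y"}
        assert sum(len(v) for k, v in p.regions.items() if k != "central") == 0

    def test_empty_input_allowed(self):
        p = dosage_partition(by_state())
        assert p.all_genes() == set()

    @given(
        d=st.sets(st.integers(0, 30)),
        u=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
    )
    @settings(max_examples=100, deadline=None)
    def test_regions_disjoint_and_exhaustive(self, d, u, b):
        s = lambda xs: {f"G{x}" for x in xs}
        p = dosage_partition(by_state(s(d), s(u), s(b)))
        regions = list(p.regions.values())
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                assert regions[i].isdisjoint(regions[j])
        assert p.all_genes() == s(d) | s(u) | s(b)


def call(ind, element, kind, state, study="S"):
    return IndividualCnvCall(ind, study, element,
                             ElementKind.MIRNA if kind == "m" else ElementKind.GENE,
                             CallState[state])


class TestInversePairs:
    def test_opposite_states_with_edge(self):
        calls = [call("11532.p1", "miR-195", "m", "DUPLICATED"),
                 call("patient1", "BDNF", "g", "DELETED")]
        (p,) = find_inverse_pairs(calls, [predicted("miR-195", "BDNF")])
        assert (p.mirna_state, p.gene_state) == (CallState.DUPLICATED, CallState.DELETED)
        assert p.mirna_individuals == {"11532.p1"} and p.gene_individuals == {"patient1"}

    def test_same_state_is_not_inverse(self):
        calls = [call("i1", "m", "m", "DELETED"), call("i2", "g", "g", "DELETED")]
        assert find_inverse_pairs(calls, [predicted("m", "g")]) == []

    def test_no_edge_no_pair(self):
        calls = [call("i1", "m", "m", "DELETED"), call("i2", "g", "g", "DUPLICATED")]
        assert find_inverse_pairs(calls, [predicted("m", "other")]) == []

    def test_both_orientations_emitted(self):
        calls = [
            call("i1", "m", "m", "DELETED"), call("i2", "m", "m", "DUPLICATED"),
            call("i3", "g", "g", "DELETED"), call("i4", "g", "g", "DUPLICATED"),
        ]
        pairs = find_inverse_pairs(calls, [predicted("m", "g")])
        orientations = {(p.mirna_state, p.gene_state) for p in pairs}
        assert orientations == {(CallState.DELETED, CallState.DUPLICATED),
                                (CallState.DUPLICATED, CallState.DELETED)}

    def test_hub_restriction(self):
        calls = [call("i1", "m1", "m", "DELETED"), call("i2", "m2", "m", "DELETED"),
                 call("i3", "g", "g", "DUPLICATED")]
        edges = [predicted("m1", "g"), predicted("m2", "g")]
        pairs = find_inverse_pairs(calls, edges, hub_mirnas={"m1"})
        assert {p.mirna_id for p in pairs} == {"m1"}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_oracle_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        mirnas = [f"m{i}" for i in range(8)]
        genes = [f"G{i}" for i in range(10)]
        calls = [
            call(f"i{k}",
                 rng.choice(mirnas) if rng.random() < 0.5 else rng.choice(genes),
                 "m" if rng.random() < 0.5 else "g",
                 "DELETED" if rng.random() < 0.5 else "DUPLICATED")
            for k in range(60)
        ]
        # element kind must match the id family to be meaningful
        calls = [c for c in calls
                 if (c.element_id.startswith("m")) == (c.element_kind is ElementKind.MIRNA)]
        edges = [predicted(m, g) for m in mirnas for g in genes if rng.random() < 0.2]
        got = {(p.mirna_id, p.gene_symbol, p.mirna_state.value, p.gene_state.value)
               for p in find_inverse_pairs(calls, edges)}
        assert got == brute_inverse_pairs(calls, edges)
        shuffled = find_inverse_pairs(list(reversed(calls)), list(reversed(edges)))
        assert [(p.mirna_id, p.gene_symbol) for p in shuffled] \
            == sorted((p.mirna_id, p.gene_symbol) for p in find_inverse_pairs(calls, edges))


class TestTfLoops:
    def test_dual_loop_example(self):
        edges = [predicted("m", "G1"), predicted("m", "G9")]
        tf_edges = [predicted("m", "t")]
        regulons = [TfRegulon("t", {"G1", "G2"})]
        loops, summary = assemble_tf_loops(edges, tf_edges, regulons, GeneSet("d", {"G1", "G2"}))
        modes = {(l.mode, l.affected_genes) for l in loops if l.tf_id == "t"}
        assert (LoopMode.TF_MEDIATED, frozenset({"G1", "G2"})) in modes
        assert (LoopMode.DUAL, frozenset({"G1"})) in modes

    def test_no_tf_edges_only_direct(self):
        loops, _ = assemble_tf_loops([predicted("m", "G1")], [], [], GeneSet("d", {"G1"}))
        assert [l.mode for l in loops] == [LoopMode.DIRECT]

    def test_union_coverage_counts(self):
        edges = [predicted("m", "G1"), predicted("m", "G3"), predicted("m", "G4")]
        regulons = [TfRegulon("t1", {"G1"}), TfRegulon("t2", {"G1", "G3"})]
        disease = GeneSet("d", {"G1", "G3", "G4"})
        _, summary = assemble_tf_loops(edges, [predicted("m", "t1"), predicted("m", "t2")],
                                       regulons, disease)
        assert summary.per_tf_counts == {"t1": 1, "t2": 2}
        assert summary.covered_genes == {"G1", "G3"}
        assert summary.coverage_fraction == pytest.approx(2 / 3)

    def test_dual_subset_of_tf_mediated_and_fraction_bounded(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(20)]
        edges = [predicted("m1", g) for g in genes[:10]] + [predicted("m2", g) for g in genes[5:15]]
        tf_edges = [predicted("m1", "t1"), predicted("m2", "t2")]
        regulons = [TfRegulon("t1", set(rng.choice(genes, 8, replace=False))),
                    TfRegulon("t2", set(rng.choice(genes, 8, replace=False)))]
        loops, summary = assemble_tf_loops(edges, tf_edges, regulons, GeneSet("d", set(genes)))
        dual = {(l.mirna_id, l.tf_id) for l in loops if l.mode is LoopMode.DUAL}
        mediated = {(l.mirna_id, l.tf_id) for l in loops if l.mode is LoopMode.TF_MEDIATED}
        assert dual <= mediated
        assert 0 <= summary.coverage_fraction <= 1


class TestBiogenesis:
    def test_default_machinery_has_thirteen_genes(self):
        assert len(MACHINERY_GENES) == 13
        assert "DICER1" in MACHINERY_GENES and "RNASEN" in MACHINERY_GENES

    def test_regulator_counts(self):
        edges = [predicted(f"m{i}", "DICER1") for i in range(30)]
        edges += [predicted("m0", "XPO5"), predicted("m0", "NOT_MACHINERY")]
        net, counts = biogenesis_subnetwork(edges)
        assert counts["DICER1"] == 30
        assert counts["XPO5"] == 1
        assert counts["AGO1"] == 0          # retained with zero regulators
        assert "AGO1" in net.gene_nodes
        assert "NOT_MACHINERY" not in net.gene_nodes

    def test_edge_set_equals_filter_oracle(self):
        rng = np.random.default_rng(4)
        genes = list(MACHINERY_GENES.symbols) + [f"g{i}" for i in range(20)]
        edges = [predicted(f"m{i}", str(rng.choice(genes))) for i in range(200)]
        edges = list({(e.mirna_id, e.gene_symbol): e for e in edges}.values())
        net, _counts = biogenesis_subnetwork(edges)
        expected = {(e.mirna_id, e.gene_symbol) for e in edges
                    if e.gene_symbol in MACHINERY_GENES.symbols}
        assert set(net.edges) == expected
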