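import numpy as np
import pytest

from cnvmirnet.netstats import (
    compare_networks,
    knockout_analysis,
    ks_two_sample,
    poisson_count_test,
    sample_null_mirnas,
)
from cnvmirnet.regnet import node_properties
from conftest import make_network


class TestNullSampling:
    def test_forced_sample_returns_all_remaining(self):
        universe = {f"m{i}" for i in range(100)}
        exclude = {f"m{i}" for i in range(71)}
        assert sample_null_mirnas(universe, exclude, 29, seed=1) == universe - exclude

    def test_deterministic_under_seed(self):
        universe = {f"m{i}" for i in range(500)}
        exclude = {f"m{i}" for i in range(71)}
        a = sample_null_mirnas(universe, exclude, 71, seed=9)
        b = sample_null_mirnas(universe, exclude, 71, seed=9)
        assert a == b and a.isdisjoint(exclude) and len(a) == 71

    def test_two_seeds_overlap_near_hypergeometric_expectation(self):
        universe = {f"m{i}" for i in range(571)}
        exclude = {f"m{i}" for i in range(71)}
        overlaps = [
            len(sample_null_mirnas(universe, exclude, 71, seed=2 * s)
                & sample_null_mirnas(universe, exclude, 71, seed=2 * s + 1))
            for s in range(40)
        ]
        assert np.mean(overlaps) == pytest.approx(71 * 71 / 500, abs=3 * np.std(overlaps) / np.sqrt(40))

    def test_shortfall_reported(self):
        with pytest.raises(ValueError, match="short by 2"):
            sample_null_mirnas({"a", "b", "c"}, {"a"}, 4, seed=0)


class TestKs:
    def test_identical_samples(self):
        r = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert r.d_statistic == 0 and r.p_value == 1

    def test_disjoint_samples_exact(self):
        r = ks_two_sample([1, 2, 3], [4, 5, 6], "exact")
        assert r.d_statistic == 1.0
        assert r.p_value == pytest.approx(2 / 20)  # 2 of C(6,3) assignments reach D=1

    def test_interleaved_example(self):
        assert ks_two_sample([1, 3], [2, 4]).d_statistic == pytest.approx(0.5)

    def test_symmetry_and_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(0.5, size=40)
        a = ks_two_sample(x, y)
        b = ks_two_sample(y, x)
        assert a.d_statistic == b.d_statistic and a.p_value == b.p_value
        c = ks_two_sample(np.exp(x), np.exp(y))  # strictly monotone transform
        assert c.d_statistic == pytest.approx(a.d_statistic)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_exact_matches_scipy_exact(self):
        from scipy import stats

        rng = np.random.default_rng(10)
        for _ in range(10):
            x, y = rng.normal(size=25), rng.normal(0.4, size=30)
            mine = ks_two_sample(x, y, "exact").p_value
            ref = stats.ks_2samp(x, y, method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_exact_close_to_asymptotic_at_n50(self):
        """The corrected asymptotic tail tracks the exact permutation p to
        within ~0.05 at n = m = 50 (the worst gap sits at mid-range p)."""
        rng = np.random.default_rng(77)
        for _ in range(15):
            x, y = rng.normal(size=50), rng.normal(size=50)
            pe = ks_two_sample(x, y, "exact").p_value
            pa = ks_two_sample(x, y).p_value
            assert abs(pe - pa) < 0.05


class TestCompareNetworks:
    def test_identical_networks_all_null(self):
        net = make_network([("m1", "g1"), ("m1", "g2"), ("m2", "g2")])
        for r in compare_networks(net, net):
            assert r.d_statistic == 0 and r.p_value == 1 and r.p_adjusted == 1

    def test_matches_direct_ks_on_degree_vectors(self):
        path = make_network([("m1", "g1"), ("m2", "g1"), ("m2", "g2"), ("m3", "g2")])
        star = make_network([("hub", f"g{i}") for i in range(6)])
        (r,) = compare_networks(path, star, ["degree"])
        direct = ks_two_sample(
            node_properties(path)["degree"].to_numpy(),
            node_properties(star)["degree"].to_numpy(),
        )
        assert r.d_statistic == direct.d_statistic and r.p_value == direct.p_value

    def test_requested_properties_in_order(self):
        net = make_network([("m", "g")])
        results = compare_networks(net, net, ["degree", "closeness"])
        assert [r.property_name for r in results] == ["degree", "closeness"]

    def test_unknown_property_lists_valid_names(self):
        net = make_network([("m", "g")])
        with pytest.raises(ValueError, match="radiality"):
            compare_networks(net, net, ["pagerank"])


class TestPoisson:
    def test_equal_counts_null(self):
        assert poisson_count_test(7, 7) == (0.0, 1.0)

    def test_wald_hand_value(self):
        z, p = poisson_count_test(2, 10)
        assert z == pytest.approx(8 / np.sqrt(12))
        assert p == pytest.approx(0.0209, abs=2e-4)

    def test_exact_conditional_binomial_enumeration(self):
        _, p = poisson_count_test(2, 10, "exact_conditional")
        assert p == pytest.approx(158 / 4096)

    def test_zero_information_rejected(self):
        with pytest.raises(ValueError):
            poisson_count_test(0, 0)

    def test_wald_exact_agree_for_separated_counts(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            x1, x2 = rng.poisson(30), rng.poisson(90)
            if x1 + x2 < 100:
                continue
            _, pw = poisson_count_test(x1, x2)
            _, pe = poisson_count_test(x1, x2, "exact_conditional")
            assert abs(pw - pe) < 0.02


class TestKnockout:
    def test_star_center_removal(self, star_network):
        (rec,) = knockout_analysis(star_network, ["hub"])
        assert rec.global_before.connected_components == 1
        assert rec.global_after.connected_components == 5
        assert rec.global_after.isolated_nodes == 5
        z, p, method = rec.tests["connected_components"]
        assert z == pytest.approx(4 / np.sqrt(6)) and method == "wald"
        assert rec.tests["isolated_nodes"] is not None

    def test_star_leaf_removal_keeps_one_component(self, star_network):
        (rec,) = knockout_analysis(star_network, ["g0"])
        assert rec.global_after.connected_components == 1
        assert rec.global_after.isolated_nodes == 0
        assert rec.tests["isolated_nodes"] is None  # 0 -> 0: no information

    def test_degree_zero_node_changes_nothing_but_n(self, star_network):
        star_network.gene_nodes.add("lonely")
        (rec,) = knockout_analysis(star_network, ["lonely"])
        assert rec.global_after.connected_components == rec.global_before.connected_components - 1
        assert not rec.density_changed or rec.global_before.density != rec.global_after.density

    def test_cycle_removal_adds_at_most_one_component(self):
        # C8 as bipartite cycle m0-g0-m1-g1-...-m0
        pairs = []
        for i in range(4):
            pairs += [(f"m{i}", f"g{i}"), (f"m{(i + 1) % 4}", f"g{i}")]
        net = make_network(pairs)
        for rec in knockout_analysis(net, [f"m{i}" for i in range(4)]):
            delta = rec.global_after.connected_components - rec.global_before.connected_components
            assert delta <= 1

    def test_independent_vs_cumulative(self, star_network):
        nodes = ["g0", "g1"]
        indep = knockout_analysis(star_network, nodes)
        assert all(r.global_before.connected_components == 1 for r in indep)
        cumul = knockout_analysis(star_network, nodes, cumulative=True)
        assert cumul[1].global_before.isolated_nodes == indep[0].global_after.isolated_nodes

    def test_unknown_node_rejected(self, star_network):
        with pytest.raises(KeyError):
            knockout_analysis(star_network, ["nope"])
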