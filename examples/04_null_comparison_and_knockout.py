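"""Null-network comparison (two-sample KS) and hub-knockout robustness.

Simulates a prediction compendium with planted hub miRNAs, builds the network,
compares its per-node metric distributions against a network built from an
equal number of resampled non-hub miRNAs, then removes the top hub and tests
the change in connected components / isolated nodes with Poisson count tests.
"""
from cnvmirnet.netstats import compare_networks, knockout_analysis, sample_null_mirnas
from cnvmirnet.regnet import build_bipartite, consensus_targets, rank_hubs
from cnvmirnet.synthgen import SimulationConfig, simulate_bundle

cfg = SimulationConfig(seed=3, n_chrom=4, n_cnvs=30, n_mirnas=40, n_genes=300,
                       n_planted_hubs=4, hub_target_count=60, background_target_count=10,
                       n_individuals=5, n_tfs=2)
bundle = simulate_bundle(cfg)
edges = consensus_targets(bundle.predictions + bundle.validated)

hub_ids = set(bundle.planted_hubs)
hub_net = build_bipartite([e for e in edges if e.mirna_id in hub_ids])
null_ids = sample_null_mirnas({m.mirna_id for m in bundle.mirnas}, hub_ids,
                              n=len(hub_ids), seed=cfg.seed)
null_net = build_bipartite([e for e in edges if e.mirna_id in null_ids])

print(f"hub network: {hub_net.n_nodes} nodes / {hub_net.n_edges} edges; "
      f"null network: {null_net.n_nodes} nodes / {null_net.n_edges} edges")
print()
print("two-sample KS on per-node metric distributions (BH-adjusted):")
print("metric                      D       p        p_adj")
for r in compare_networks(hub_net, null_net, ["degree", "avg_shortest_path",
                                              "closeness", "radiality"]):
    print(f"{r.property_name:25s} {r.d_statistic:6.3f}  {r.p_value:8.4g} {r.p_adjusted:8.4g}")
print()
print("Planted hubs target ~6x more genes than resampled miRNAs, so the degree")
print("distributions separate; note the per-node path metrics are dependent")
print("within a network, making this comparison anticonservative (see docs).")
print()

(top_hub, degree), = rank_hubs(hub_net, k=1)
(rec,) = knockout_analysis(hub_net, [top_hub])
z, p_wald, _ = rec.tests["isolated_nodes"]
print(f"knocking out {top_hub} (degree {degree}):")
print(f"  connected components {rec.global_before.connected_components} -> "
      f"{rec.global_after.connected_components}")
print(f"  isolated nodes {rec.global_before.isolated_nodes} -> "
      f"{rec.global_after.isolated_nodes}  (Poisson Wald z={z:.2f}, p={p_wald:.4g})")
print(f"  diameter changed: {rec.diameter_changed}, density changed: {rec.density_changed}")
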