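"""End-to-end orchestration: filter -> map -> network -> compare -> knockout ->
dosage -> loops -> biogenesis, from one config, with a run manifest.

The config is a YAML mapping with one section per stage mirroring the CLI
flags. Inputs come either from a ``simulate`` section (the synthetic
generator) or an ``inputs`` section of file paths. Every stage writes its
artifact before downstream stages run, so partial output survives a failure;
the manifest records input checksums, per-stage counts and the failed stage if
any. Identical config + seed reproduces identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cnv_landscape import compute_cnv_density, select_consistent_cnvs
from .dosage_loops import (
    MACHINERY_GENES,
    assemble_tf_loops,
    biogenesis_subnetwork,
    dosage_partition,
    find_inverse_pairs,
)
from .mirna_mapping import classify_mirna_state, overlap_mirnas
from .netstats import compare_networks, knockout_analysis, sample_null_mirnas
from .regnet import (
    DEFAULT_SOURCES,
    build_bipartite,
    consensus_targets,
    degree_distribution_fit,
    global_properties,
    node_properties,
    rank_hubs,
    restrict_to_gene_set,
)
from .synthgen import SimulationConfig, simulate_inputs
from .tables_io import (
    CnvState,
    Region,
    read_bed,
    read_cnv_table,
    read_gene_set,
    read_genome_table,
    read_individual_calls,
    read_predictions,
    read_tf_regulons,
    write_network,
    TableDialect,
)

log = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as handle:
            return yaml.safe_load(handle) or {}
    return dict(config)


def run_pipeline(config, outdir: str | Path) -> dict:
    """Run the full analysis chain; returns the manifest (also written to disk).

    ``config`` is a YAML path or an equivalent mapping. Raises on the first
    failing stage after writing a manifest that names it.
    """
    cfg = _load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest: dict = {
        "config": cfg,
        "seed": seed,
        "version": __version__,
        "inputs": {},
        "counts": {},
        "failed_stage": None,
    }
    stage = "setup"
    try:
        # ------------------------------------------------ inputs
        stage = "inputs"
        if "simulate" in cfg:
            sim = dict(cfg["simulate"] or {})
            sim.pop("preset", None)  # the preset is simply the defaults
            sim.setdefault("seed", seed)
            paths = simulate_inputs(SimulationConfig(**sim), outdir / "inputs")
        else:
            raw = cfg.get("inputs")
            if not raw:
                raise KeyError("config needs an 'inputs' or 'simulate' section")
            for key in ("genome", "cnvs", "mirnas", "predictions", "disease_genes"):
                if key not in raw:
                    raise KeyError(f"config inputs section is missing required key '{key}'")
            paths = {}
            for name, value in raw.items():
                if name == "predictions":
                    for i, p in enumerate([value] if isinstance(value, str) else value):
                        paths[f"predictions_{i}"] = Path(p)
                else:
                    paths[name] = Path(value)
        manifest["inputs"] = {name: _sha256(p) for name, p in sorted(paths.items())}

        dialect = TableDialect(coords=cfg.get("coords", "0-based-half-open"))
        genome = read_genome_table(paths["genome"])
        cnvs = read_cnv_table(paths["cnvs"], dialect)
        mirnas = read_bed(paths["mirnas"])
        prediction_paths = [p for name, p in sorted(paths.items()) if name.startswith("predictions_")]
        predictions = read_predictions(prediction_paths)
        if "validated" in paths:
            predictions += read_predictions(paths["validated"])
        master = read_gene_set(paths["disease_genes"], "disease_genes")
        manifest["counts"]["cnvs_catalogued"] = len(cnvs)
        manifest["counts"]["mirna_universe"] = len(mirnas)

        # ------------------------------------------------ density
        stage = "density"
        density = compute_cnv_density(cnvs, genome)
        pd.DataFrame([asdict(d) for d in density]).to_csv(outdir / "density.tsv", sep="\t", index=False)
        manifest["counts"]["enriched_chromosomes"] = sum(d.enriched for d in density)

        # ------------------------------------------------ filter
        stage = "filter"
        fcfg = cfg.get("filter", {})
        selected = select_consistent_cnvs(
            cnvs, fcfg.get("min_studies_single", 2), fcfg.get("min_studies_both", 6)
        )
        pd.DataFrame(
            [
                {
                    "locus_id": c.locus_id,
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "variation_class": c.variation_class.value,
                    "study_count": c.study_count,
                }
                for c in selected
            ]
        ).to_csv(outdir / "selected_cnvs.tsv", sep="\t", index=False)
        manifest["counts"]["cnvs_selected"] = len(selected)

        # ------------------------------------------------ map-mirnas
        stage = "map-mirnas"
        policy = cfg.get("map", {}).get("policy", "full_containment")
        hits = overlap_mirnas(selected, mirnas, policy)
        states = classify_mirna_state(hits, selected)
        pd.DataFrame(
            [
                {"mirna_id": a.mirna_id, "cnv_state": a.cnv_state.value,
                 "locus_ids": ",".join(sorted(a.locus_ids))}
                for a in states
            ]
        ).to_csv(outdir / "mirna_states.tsv", sep="\t", index=False)
        cls_of = {c.locus_id: c for c in selected}
        pd.DataFrame(
            [
                {"locus_id": lid, "variation_class": cls_of[lid].variation_class.value,
                 "study_count": cls_of[lid].study_count,
                 "mirnas": ",".join(sorted(members))}
                for lid, members in sorted(hits.items())
            ]
        ).to_csv(outdir / "locus_mirnas.tsv", sep="\t", index=False)
        manifest["counts"]["cnv_mirnas"] = len(states)
        manifest["counts"]["mirna_bearing_loci"] = sum(1 for m in hits.values() if m)

        # ------------------------------------------------ network
        stage = "build-network"
        ncfg = cfg.get("network", {})
        sources = frozenset(ncfg.get("required_sources", sorted(DEFAULT_SOURCES)))
        edges_all = consensus_targets(
            predictions, sources, ncfg.get("min_seed", 7), Region(ncfg.get("region", "UTR3"))
        )
        cnv_mirna_ids = {a.mirna_id for a in states}
        cnv_edges_allgenes = [e for e in edges_all if e.mirna_id in cnv_mirna_ids]
        edges = restrict_to_gene_set(cnv_edges_allgenes, master)
        net = build_bipartite(edges)
        write_network(net, outdir / "network.graphml", "graphml", allow_empty=True)
        write_network(net, outdir / "network_edges.tsv", "edge_tsv", allow_empty=True)
        props = node_properties(net)
        props.rename_axis("node").to_csv(outdir / "node_properties.tsv", sep="\t")
        glob = global_properties(net)
        pd.DataFrame([asdict(glob)]).to_csv(outdir / "global_properties.tsv", sep="\t", index=False)
        k = cfg.get("hubs", {}).get("k", 10)
        hubs = rank_hubs(net, k=k) if net.mirna_nodes else []
        pd.DataFrame(hubs, columns=["node", "degree"]).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
        try:
            exponent, r2 = degree_distribution_fit(net)
            manifest["counts"]["power_law"] = {"exponent": exponent, "r_squared": r2}
        except ValueError:
            manifest["counts"]["power_law"] = None
        manifest["counts"]["network_nodes"] = net.n_nodes
        manifest["counts"]["network_edges"] = net.n_edges

        # ------------------------------------------------ compare vs null
        stage = "compare"
        ccfg = cfg.get("compare", {})
        universe = {m.mirna_id for m in mirnas}
        n_null = len(cnv_mirna_ids & {e.mirna_id for e in edges})
        results = []
        if n_null and len(universe - cnv_mirna_ids) >= n_null:
            null_ids = sample_null_mirnas(universe, cnv_mirna_ids, n_null, seed)
            null_edges = restrict_to_gene_set(
                [e for e in edges_all if e.mirna_id in null_ids], master
            )
            if null_edges:
                null_net = build_bipartite(null_edges)
                results = compare_networks(
                    net, null_net,
                    ccfg.get("properties"), ccfg.get("method", "asymptotic"),
                    ccfg.get("side"),
                )
        pd.DataFrame([asdict(r) for r in results]).to_csv(outdir / "compare.tsv", sep="\t", index=False)
        manifest["counts"]["compared_properties"] = len(results)

        # ------------------------------------------------ knockout
        stage = "knockout"
        records = knockout_analysis(net, [h for h, _d in hubs]) if hubs else []
        rows = []
        for r in records:
            wald_cc = r.tests.get("connected_components")
            exact_cc = r.tests.get("connected_components_exact")
            wald_iso = r.tests.get("isolated_nodes")
            exact_iso = r.tests.get("isolated_nodes_exact")
            rows.append(
                {
                    "node": r.removed_node,
                    "components_before": r.global_before.connected_components,
                    "components_after": r.global_after.connected_components,
                    "isolated_before": r.global_before.isolated_nodes,
                    "isolated_after": r.global_after.isolated_nodes,
                    "components_z": wald_cc[0] if wald_cc else None,
                    "components_p_wald": wald_cc[1] if wald_cc else None,
                    "components_p_exact": exact_cc[1] if exact_cc else None,
                    "isolated_z": wald_iso[0] if wald_iso else None,
                    "isolated_p_wald": wald_iso[1] if wald_iso else None,
                    "isolated_p_exact": exact_iso[1] if exact_iso else None,
                    "diameter_changed": r.diameter_changed,
                    "cpl_changed": r.cpl_changed,
                    "density_changed": r.density_changed,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "knockout.tsv", sep="\t", index=False)
        manifest["counts"]["knockouts"] = len(rows)

        # ------------------------------------------------ dosage
        stage = "dosage"
        state_of = {a.mirna_id: a.cnv_state for a in states}
        targets_by_state: dict[CnvState, set[str]] = {s: set() for s in CnvState}
        for edge in edges:
            targets_by_state[state_of[edge.mirna_id]].add(edge.gene_symbol)
        partition = dosage_partition(targets_by_state)
        pd.DataFrame(
            [
                {"gene": gene, "region": region, "dosage_label": partition.labels[region].value}
                for region, genes in partition.regions.items()
                for gene in sorted(genes)
            ]
        ).to_csv(outdir / "dosage.tsv", sep="\t", index=False)
        manifest["counts"]["dosage_regions"] = partition.sizes()

        # ------------------------------------------------ inverse pairs
        stage = "inverse-pairs"
        pairs = []
        if "calls" in paths:
            calls = read_individual_calls(paths["calls"])
            hub_set = {h for h, _d in hubs} if cfg.get("inverse_pairs", {}).get("hubs_only", True) else None
            pairs = find_inverse_pairs(calls, edges, hub_set)
        pd.DataFrame(
            [
                {
                    "mirna_id": p.mirna_id, "gene_symbol": p.gene_symbol,
                    "mirna_state": p.mirna_state.value, "gene_state": p.gene_state.value,
                    "mirna_individuals": ",".join(sorted(p.mirna_individuals)),
                    "gene_individuals": ",".join(sorted(p.gene_individuals)),
                }
                for p in pairs
            ]
        ).to_csv(outdir / "inverse_pairs.tsv", sep="\t", index=False)
        manifest["counts"]["inverse_pairs"] = len(pairs)

        # ------------------------------------------------ TF loops
        stage = "loops"
        loops, summary = [], None
        if "mirna_tf" in paths and "regulons" in paths:
            tf_rows = read_predictions(paths["mirna_tf"])
            tf_edges = consensus_targets(tf_rows, sources)  # validated rows pass through
            tf_edges = [e for e in tf_edges if e.mirna_id in cnv_mirna_ids]
            regulons = read_tf_regulons(paths["regulons"])
            loops, summary = assemble_tf_loops(edges, tf_edges, regulons, master)
        pd.DataFrame(
            [
                {"mirna_id": l.mirna_id, "tf_id": l.tf_id or "", "mode": l.mode.value,
                 "affected_genes": ",".join(sorted(l.affected_genes))}
                for l in loops
            ]
        ).to_csv(outdir / "loops.tsv", sep="\t", index=False)
        manifest["counts"]["tf_loops"] = len(loops)
        if summary is not None:
            manifest["counts"]["tf_coverage_fraction"] = summary.coverage_fraction

        # ------------------------------------------------ biogenesis
        stage = "biogenesis"
        bio_net, bio_counts = biogenesis_subnetwork(cnv_edges_allgenes, MACHINERY_GENES)
        write_network(bio_net, outdir / "biogenesis.graphml", "graphml", allow_empty=True)
        pd.DataFrame(
            sorted(bio_counts.items()), columns=["gene", "n_regulating_mirnas"]
        ).to_csv(outdir / "biogenesis_counts.tsv", sep="\t", index=False)
        manifest["counts"]["biogenesis_edges"] = bio_net.n_edges
    except Exception:
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
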