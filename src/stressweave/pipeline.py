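"""End-to-end pipeline: enhance -> cluster -> hubs/enrich -> associate ->
variants -> integrate, with every artifact written to the output
directory and a machine-readable JSON run report."""

from __future__ import annotations

import json
import logging
import time
import warnings
from pathlib import Path

import pandas as pd

from . import annotation, association, clustering, enhance, integration, synthetic, variants
from . import io as swio
from .config import PipelineConfig
from .errors import StressweaveError

logger = logging.getLogger(__name__)


def _load_inputs(config: PipelineConfig):
    if config.use_synthetic:
        spec = synthetic.SyntheticSpec(**{"seed": config.seed, **config.synthetic})
        ds = synthetic.generate_all(spec)
        return ds, ds.truth
    paths = config.inputs
    ds = synthetic.SyntheticDataset(
        spec=None,
        edges=swio.read_edges(paths["edges"]),
        fold_changes=swio.read_degs(paths["degs"]),
        expression=swio.read_expression(paths["expression"]) if "expression" in paths else None,
        phenotypes=swio.read_phenotypes(paths["phenotypes"]) if "phenotypes" in paths else None,
        variant_records=swio.read_vcf(paths["vcf"]) if "vcf" in paths else [],
        consequences=(
            swio.read_consequences(paths["consequences"])
            if "consequences" in paths
            else pd.DataFrame(columns=["variant", "gene", "consequence"])
        ),
        terms=swio.read_gmt(paths["gmt"]) if "gmt" in paths else {},
        perturbations=(
            pd.read_csv(paths["perturbations"])
            if "perturbations" in paths
            else pd.DataFrame(columns=["pathway", "direction", "fold_enrichment", "fdr"])
        ),
        truth=None,
        phenotype_directions=dict(config.phenotype_directions),
    )
    return ds, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and return the run report dict.

    The report is also written to ``<outdir>/run_report.json``. A stage
    failure leaves earlier artifacts in place and re-raises after the
    report (flagging the failed stage) is written.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}, "warnings": []}
    stage = "inputs"
    t0 = time.perf_counter()

    def _done(name, **counts):
        report["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 4), **counts,
        }

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")

            ds, truth = _load_inputs(config)
            if config.use_synthetic:
                swio.write_edges(ds.edges, outdir / "edges.tsv")
                swio.write_degs(ds.fold_changes, outdir / "degs.tsv")
                swio.write_gmt(ds.terms, outdir / "terms.gmt")
                swio.write_vcf(ds.variant_records, outdir / "variants.vcf")
                swio.write_consequences(ds.consequences, outdir / "consequences.tsv")
                swio.write_expression(ds.expression, outdir / "expression.tsv")
                swio.write_phenotypes(ds.phenotypes, outdir / "phenotypes.csv")
                ds.perturbations.to_csv(outdir / "perturbations.csv", index=False)
            _done("inputs", n_edges=len(ds.edges), n_genes=len(ds.fold_changes))

            stage = "enhance"
            t0 = time.perf_counter()
            deg_filter = enhance.DEGFilter(
                fdr_max=config.deg_fdr_max,
                abs_log2fc_min=config.deg_abs_log2fc_min,
                pvalue_max=config.deg_pvalue_max,
            )
            degs = enhance.filter_degs(ds.fold_changes, deg_filter)
            graph = enhance.build_enhanced_graph(
                ds.edges, degs, config.ppi_confidence, config.score_mode
            )
            swio.write_graphml(graph, outdir / "enhanced_graph.graphml")
            swio.write_edge_attributes(graph, outdir / "enhanced_edges.tsv")
            _done("enhance", n_degs=len(degs), n_nodes=graph.number_of_nodes(),
                  n_edges=graph.number_of_edges())

            stage = "cluster"
            t0 = time.perf_counter()
            best_r, solution = clustering.tune_inflation(graph, config.inflation_grid)
            log2fc = {g: graph.nodes[g]["log2fc"] for g in graph.nodes}
            clustering.annotate_solution(solution, log2fc)
            selected = clustering.filter_clusters(solution, config.cluster_min_size)
            assign = pd.DataFrame(
                [
                    {"gene": g, "cluster": c, "log2fc": log2fc[g]}
                    for g, c in sorted(solution.partition.items())
                ]
            )
            assign.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    {"cluster": cid, "selected": cid in selected, **vars(st)}
                    for cid, st in sorted(solution.stats.items())
                ]
            ).to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)
            _done("cluster", inflation=best_r, modularity=solution.modularity,
                  n_clusters=solution.n_clusters, n_selected=len(selected),
                  converged=solution.converged)

            stage = "hubs"
            t0 = time.perf_counter()
            part_sel = {
                g: c for g, c in solution.partition.items() if c in selected
            }
            records = annotation.centralities(graph, part_sel)
            records.to_csv(outdir / "centralities.tsv", sep="\t", index=False)
            hubs = annotation.select_hubs(records, config.hub_top_k, config.hub_min_metrics)
            hub_genes = sorted({g for hh in hubs.values() for g in hh})
            pd.DataFrame(
                [{"cluster": c, "gene": g} for c, hh in sorted(hubs.items()) for g in hh]
            ).to_csv(outdir / "hubs.tsv", sep="\t", index=False)
            _done("hubs", n_hubs=len(hub_genes))

            stage = "enrich"
            t0 = time.perf_counter()
            universe = set(ds.fold_changes["gene"])
            labels, enr_rows = {}, []
            for cid in selected:
                members = set(solution.members(cid))
                results = annotation.enrich_terms(members, universe, ds.terms)
                for r in results:
                    r.cluster = cid
                    enr_rows.append(vars(r))
                labels[cid] = annotation.label_cluster(
                    results, fdr_max=config.enrichment_fdr
                )
            pd.DataFrame(enr_rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            _done("enrich", n_labeled=sum(v != "unlabeled" for v in labels.values()))

            stage = "associate"
            t0 = time.perf_counter()
            assoc_records = []
            if ds.expression is not None and ds.phenotypes is not None:
                expr = ds.expression.loc[ds.expression.index.isin(set(assign["gene"]))]
                assoc_records = association.associate_all(
                    expr, ds.phenotypes,
                    ess=config.association_ess, threshold=config.association_threshold,
                )
                pd.DataFrame([vars(r) for r in assoc_records]).to_csv(
                    outdir / "associations.tsv", sep="\t", index=False
                )
            _done("associate", n_passing=sum(r.passes for r in assoc_records))

            stage = "variants"
            t0 = time.perf_counter()
            var_table = variants.gene_impact_table(
                ds.variant_records, ds.consequences
            )
            var_table.to_csv(outdir / "variant_impacts.tsv", sep="\t", index=False)
            summary = variants.summarize_variants(var_table)
            summary["zygosity_by_tier"].to_csv(outdir / "variant_summary.tsv", sep="\t")
            _done("variants", n_distinct=summary["n_distinct_variants"],
                  n_rows=summary["n_rows"])

            stage = "integrate"
            t0 = time.perf_counter()
            gene_table = assign.copy()
            gene_table["fermentation_ethanol"] = gene_table["gene"].isin(
                config.fermentation_genes
            )
            gene_table["ros_redox"] = gene_table["gene"].isin(config.ros_genes)
            net = integration.assemble(
                gene_table, ds.terms, ds.perturbations, assoc_records, var_table,
                phenotype_directions=ds.phenotype_directions,
                fdr_max=config.enrichment_fdr,
            )
            flagged = set(config.fermentation_genes) | set(config.ros_genes)
            anchors = set(hub_genes) | flagged
            if not anchors:
                warnings.warn("no anchor genes (hubs or flags); model is empty")
            sub = integration.extract_anchor_subnetwork(net, set(hub_genes), flagged)
            swio.write_network_json(net, outdir / "integration_full.json")
            swio.write_network_json(sub, outdir / "integration_model.json")
            model = integration.tabulate_model(sub)
            model.to_csv(outdir / "model_genes.tsv", sep="\t", index=False)
            _done(
                "integrate",
                n_edges=net.number_of_edges(),
                n_model_genes=len(model),
                n_positive=int(model["n_positive"].sum()) if len(model) else 0,
                n_negative=int(model["n_negative"].sum()) if len(model) else 0,
            )

            report["warnings"] = sorted({str(w.message) for w in caught})
    except StressweaveError:
        report["failed_stage"] = stage
        (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
        raise

    report["inflation"] = report["stages"]["cluster"]["inflation"]
    report["modularity"] = report["stages"]["cluster"]["modularity"]
    if truth is not None:
        report["n_planted_clusters"] = len(set(truth.gene_cluster.values()))
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1))
    return report
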