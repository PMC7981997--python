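"""End-to-end orchestration of the network-pharmacology stages.

Stage order mirrors the analysis workflow: drug-likeness gating ->
target-prediction filtering -> disease-gene selection and intersection ->
differential-expression validation -> compound-target network -> PPI
filtering and hub selection -> MCODE clustering -> enrichment ->
compound-target-pathway network.  Every applied threshold and every
before/after count is logged, all stage outputs land in the output
directory as diff-able text files, and the JSON run report repeats every
funnel count so a rerun can be byte-compared.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from npharm import chem_filter, enrich, mcode, netbuild, target_disease

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Input paths and thresholds for one pipeline run."""

    compounds: str | None = None
    predictions: str | None = None
    disease: str | None = None
    expression: str | None = None
    labels: str | None = None
    ppi: str | None = None
    annotations: dict = field(default_factory=dict)  # category -> GMT path
    outdir: str = "npharm_out"
    seed: int = 0

    min_rules_passed: int = 2
    min_bas: float = 0.30
    p_min: float = 0.1
    score_min: float = 10.0
    de_fraction: float = 0.10
    ppi_threshold: float = 0.7
    top_k: int = 20
    node_score_cutoff: float = 0.2
    core_k: int = 2
    degree_cutoff: int = 2
    fdr_gate: float = 0.01
    enrich_method: str = "hypergeometric"
    n_pathways: int = 25

    def validate(self) -> None:
        checks = [
            (0 <= self.p_min <= 1, f"p_min must lie in [0, 1], got {self.p_min}"),
            (0 < self.de_fraction <= 0.5,
             f"de_fraction must lie in (0, 0.5], got {self.de_fraction}"),
            (0 <= self.ppi_threshold <= 1,
             f"ppi_threshold must lie in [0, 1], got {self.ppi_threshold}"),
            (0 <= self.min_bas <= 1, f"min_bas must lie in [0, 1], got {self.min_bas}"),
            (0 <= self.min_rules_passed <= 5,
             f"min_rules_passed must lie in [0, 5], got {self.min_rules_passed}"),
            (self.score_min >= 0, f"score_min must be >= 0, got {self.score_min}"),
            (0 < self.fdr_gate < 1, f"fdr_gate must lie in (0, 1), got {self.fdr_gate}"),
            (self.top_k >= 1, f"top_k must be >= 1, got {self.top_k}"),
            (0 <= self.node_score_cutoff < 1,
             f"node_score_cutoff must lie in [0, 1), got {self.node_score_cutoff}"),
            (self.core_k >= 0, f"core_k must be >= 0, got {self.core_k}"),
            (self.degree_cutoff >= 0,
             f"degree_cutoff must be >= 0, got {self.degree_cutoff}"),
            (self.enrich_method in ("hypergeometric", "ease"),
             f"unknown enrich_method {self.enrich_method!r}"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_inputs(config: PipelineConfig) -> dict:
    """Read the six input tables named by the config into memory."""
    required = ["compounds", "predictions", "disease", "expression", "labels", "ppi"]
    missing = [k for k in required if getattr(config, k) is None]
    if missing:
        raise ValueError(f"config lacks input paths: {missing}")
    for k in required:
        if not Path(getattr(config, k)).exists():
            raise FileNotFoundError(f"{k} table not found: {getattr(config, k)}")
    bundle = {
        "compounds": pd.read_csv(config.compounds, sep="\t"),
        "predictions": pd.read_csv(config.predictions, sep="\t"),
        "disease": pd.read_csv(config.disease, sep="\t"),
        "expression": pd.read_csv(config.expression, sep="\t", index_col=0),
        "labels": pd.read_csv(config.labels, sep="\t", index_col=0)["label"],
        "ppi": pd.read_csv(config.ppi, sep="\t"),
        "annotations": {
            category: enrich.read_gmt(path, category)
            for category, path in sorted(config.annotations.items())
        },
    }
    return bundle


def _write_gene_list(genes, path: Path) -> None:
    path.write_text("".join(f"{g}\n" for g in sorted(genes)))


def run(config: PipelineConfig, bundle: dict | None = None) -> dict:
    """Execute all stages; returns the run report (also written as JSON).

    ``bundle`` may supply the input tables directly (as produced by
    :func:`npharm.synthetic.generate_all`); otherwise they are read from
    the paths in the config.  On any stage failure the partial outputs
    are removed and :class:`PipelineError` is raised.
    """
    config.validate()
    if bundle is None:
        bundle = load_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    stage = "setup"
    try:
        report: dict = {"seed": config.seed, "thresholds": {
            "min_rules_passed": config.min_rules_passed,
            "min_bas": config.min_bas,
            "p_min": config.p_min,
            "score_min": config.score_min,
            "de_fraction": config.de_fraction,
            "ppi_threshold": config.ppi_threshold,
            "top_k": config.top_k,
            "node_score_cutoff": config.node_score_cutoff,
            "core_k": config.core_k,
            "degree_cutoff": config.degree_cutoff,
            "fdr_gate": config.fdr_gate,
        }}

        stage = "chem_filter"
        verdicts = chem_filter.select_candidates(
            bundle["compounds"], config.min_rules_passed, config.min_bas
        )
        chem_filter.write_verdicts(verdicts, _out("verdicts.tsv"))
        selected = verdicts.loc[verdicts["selected"], "compound_id"].tolist()
        logger.info(
            "chem_filter: %d compounds in, %d pass (>= %d rules, BAS >= %.2f)",
            len(verdicts), len(selected), config.min_rules_passed, config.min_bas,
        )

        stage = "target_filter"
        mapping = target_disease.filter_predictions(
            bundle["predictions"], config.p_min
        )
        mapping = {c: mapping.get(c, set()) for c in selected}
        union = target_disease.target_union(mapping)
        with_targets = target_disease.drop_targetless_compounds(selected, mapping)
        _write_gene_list(union, _out("targets_union.txt"))
        logger.info(
            "target_filter: probability >= %.2f keeps %d targets over %d/%d compounds",
            config.p_min, len(union), len(with_targets), len(selected),
        )

        stage = "disease_genes"
        disease_genes = target_disease.filter_disease_genes(
            bundle["disease"], config.score_min
        )
        _write_gene_list(disease_genes, _out("disease_genes.txt"))
        venn1 = target_disease.intersect(union, disease_genes)
        _write_gene_list(venn1.genes, _out("targets_in_disease.txt"))
        logger.info(
            "disease_genes: score >= %.1f keeps %d genes; Venn %d & %d -> %d",
            config.score_min, len(disease_genes),
            venn1.size_a, venn1.size_b, venn1.size_intersection,
        )

        stage = "expression"
        over, under = target_disease.select_top_decile_de(
            bundle["expression"], bundle["labels"], config.de_fraction
        )
        _write_gene_list(over, _out("de_over.txt"))
        _write_gene_list(under, _out("de_under.txt"))
        venn2 = target_disease.intersect(set(venn1.genes), over | under)
        final_targets = list(venn2.genes)
        _write_gene_list(final_targets, _out("final_targets.txt"))
        logger.info(
            "expression: top %.0f%% each way -> %d DE genes; Venn %d & %d -> %d",
            100 * config.de_fraction, len(over | under),
            venn2.size_a, venn2.size_b, venn2.size_intersection,
        )

        stage = "bipartite_network"
        bipartite = netbuild.build_bipartite(mapping)
        netbuild.write_sif(bipartite, _out("bipartite.sif"))
        netbuild.write_graphml(bipartite, _out("bipartite.graphml"))
        netbuild.write_metrics(bipartite, _out("bipartite_metrics.tsv"))
        compound_rank = [
            v for v in netbuild.top_k_by_degree(bipartite, bipartite.number_of_nodes())
            if bipartite.nodes[v]["kind"] == netbuild.COMPOUND
        ][:5]
        top5_means = netbuild.mean_metrics(bipartite, compound_rank)

        stage = "ppi"
        ppi_net = netbuild.filter_ppi(bundle["ppi"], config.ppi_threshold)
        netbuild.write_sif(ppi_net, _out("ppi.sif"))
        netbuild.write_graphml(ppi_net, _out("ppi.graphml"))
        netbuild.write_metrics(ppi_net, _out("ppi_metrics.tsv"))
        hubs = netbuild.top_k_by_degree(ppi_net, config.top_k)
        _write_gene_list(hubs, _out("hubs.txt"))
        hub_means = netbuild.mean_metrics(ppi_net, hubs)
        logger.info(
            "ppi: confidence > %.2f -> %d nodes, %d edges; top %d hubs kept",
            config.ppi_threshold, ppi_net.number_of_nodes(),
            ppi_net.number_of_edges(), len(hubs),
        )

        stage = "mcode"
        clusters = mcode.run_mcode(
            ppi_net,
            node_score_cutoff=config.node_score_cutoff,
            core_k=config.core_k,
            degree_cutoff=config.degree_cutoff,
        )
        mcode.write_clusters(clusters, _out("clusters.tsv"))
        logger.info("mcode: %d clusters survive post-processing", len(clusters))

        stage = "enrichment"
        terms = [t for ts in bundle["annotations"].values() for t in ts]
        result = enrich.enrich(
            final_targets, terms,
            method=config.enrich_method, fdr_gate=config.fdr_gate,
        )
        enrich.write_enrichment(result, _out("enrichment.tsv"))
        bubble = enrich.bubble_table(result, top=config.n_pathways)
        bubble.to_csv(_out("bubble.tsv"), sep="\t", index=False)
        sig_counts = (
            result.loc[result["significant"], "category"].value_counts().to_dict()
        )
        logger.info("enrichment: significant terms per category: %s", sig_counts)

        stage = "tripartite_network"
        hub_set = set(hubs)
        hub_mapping = {
            c: genes & hub_set for c, genes in mapping.items() if genes & hub_set
        }
        kegg_sig = result.loc[
            result["significant"] & (result["category"] == "KEGG")
        ].head(config.n_pathways)
        term_members = {t.term_id: t.members for t in terms}
        pathway_members = {
            tid: term_members[tid] & hub_set for tid in kegg_sig["term_id"]
        }
        if hub_mapping:
            tripartite = netbuild.build_tripartite(hub_mapping, pathway_members)
            netbuild.write_sif(tripartite, _out("tripartite.sif"))
            netbuild.write_graphml(tripartite, _out("tripartite.graphml"))
            tri_info = {
                "nodes": tripartite.number_of_nodes(),
                "edges": tripartite.number_of_edges(),
                "classes": netbuild.class_counts(tripartite),
            }
        else:
            tri_info = {"nodes": 0, "edges": 0, "classes": {}}

        stage = "report"
        report.update(
            {
                "funnel": {
                    "compounds_total": len(verdicts),
                    "compounds_selected": len(selected),
                    "compounds_with_targets": len(with_targets),
                    "target_union": len(union),
                    "disease_genes": len(disease_genes),
                    "targets_in_disease": venn1.size_intersection,
                    "final_targets": venn2.size_intersection,
                },
                "venn": {
                    "targets_vs_disease": venn1.summary(),
                    "candidates_vs_expression": venn2.summary(),
                },
                "de": {"over": len(over), "under": len(under)},
                "bipartite": {
                    "nodes": bipartite.number_of_nodes(),
                    "edges": bipartite.number_of_edges(),
                    "top_compounds": compound_rank,
                    "top_compound_means": {
                        "degree": round(top5_means[0], 4),
                        "betweenness": round(top5_means[1], 5),
                        "closeness": round(top5_means[2], 4),
                    },
                },
                "ppi": {
                    "nodes": ppi_net.number_of_nodes(),
                    "edges": ppi_net.number_of_edges(),
                    "hubs": hubs,
                    "hub_means": {
                        "degree": round(hub_means[0], 4),
                        "betweenness": round(hub_means[1], 5),
                        "closeness": round(hub_means[2], 4),
                    },
                },
                "clusters": mcode.clusters_table(clusters).to_dict("records"),
                "enrichment": {
                    "significant_per_category": {
                        k: int(v) for k, v in sorted(sig_counts.items())
                    },
                    "n_terms_tested": int(len(result)),
                },
                "tripartite": tri_info,
            }
        )
        report_path = _out("report.json")
        report_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
        return report
    except PipelineError:
        raise
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
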