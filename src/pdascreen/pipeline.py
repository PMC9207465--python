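"""End-to-end orchestration of the gene-prioritization cascade.

Stage order: rare-damaging filter -> per-variant Fisher association ->
gene-level burden test -> gene-set over-representation -> network
connectivity prioritization -> developmental-expression prioritization.
Stages communicate through typed TSV artifacts in the output directory so
any stage can be rerun or inspected standalone; the run is summarized in
a machine-readable JSON report whose bytes are identical across reruns of
the same config and inputs. An empty stage output downgrades later stages
to empty outputs with warnings, never a crash.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd

from . import __version__
from .burden import BurdenCriteria, GeneBurdenResult, burden_test, collapse_carriers
from .cohort_io import (
    CohortGenotypes,
    VariantRecord,
    read_annotations,
    read_genotypes,
    write_annotations,
    write_matrix,
)
from .enrichment import (
    EnrichmentResult,
    GeneSetCollection,
    read_gmt,
    run_ora,
    select_pathway_genes,
    significant_terms,
)
from .expression import StageExpression, expression_priority, read_expression
from .filters import FilterConfig, filter_rare_damaging
from .network import (
    InteractionNetwork,
    NetworkScore,
    prioritize_by_network,
    read_edge_list,
    read_gene_list,
    score_connectivity,
)
from .stats import (
    AssociationResult,
    format_p,
    manhattan_points,
    variant_association,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes_path: str
    sample_sheet_path: str
    annotations_path: str
    gmt_path: str
    edges_path: str
    known_list_paths: dict[str, str]
    expression_path: str
    output_dir: str
    filter_cfg: FilterConfig = field(default_factory=FilterConfig)
    burden_criteria: BurdenCriteria = field(default_factory=BurdenCriteria)
    association_mode: str = "allele"
    association_alpha: float = 0.05
    burden_alpha: float = 0.05
    ora_alpha: float = 0.05
    selected_terms: list[str] | None = None  # None: all ORA-significant terms
    network_k: int | None = None
    network_min_score: float | None = None
    network_method: str = "neighbors"
    expression_rule: str = "mean_above"
    expression_threshold: float | None = None
    seed: int | None = None  # echoed for provenance of simulated inputs

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["filter_cfg"]["damaging_func_classes"] = sorted(
            self.filter_cfg.damaging_func_classes
        )
        d["filter_cfg"]["acmg_keep"] = sorted(self.filter_cfg.acmg_keep)
        return d


@dataclass
class PipelineReport:
    stage_counts: dict[str, dict[str, int]]
    fisher_significant_variants: list[dict[str, Any]]
    burden_results: list[dict[str, Any]]
    enrichment_results: list[dict[str, Any]]
    selected_terms: list[str]
    pathway_genes: list[str]
    network_scores: list[dict[str, Any]]
    network_prioritized: list[str]
    final_genes: list[str]
    provenance: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _assoc_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "p": r.p,
                "p_rounded": format_p(r.p),
                "q": r.q,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def _burden_frame(results: Sequence[GeneBurdenResult]) -> pd.DataFrame:
    # column order mirrors the gene-level result table convention
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "case_mutation": r.table.a,
                "case_normal": r.table.b,
                "control_mutation": r.table.c,
                "control_normal": r.table.d,
                "p": r.p,
                "p_rounded": format_p(r.p),
                "q": r.q,
                "n_variants": r.n_variants_in_gene,
                "max_case_hits_single_variant": r.max_case_hits_single_variant,
                "passes": r.passes,
            }
            for r in results
        ]
    )


def _enrich_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "q": r.q,
            }
            for r in results
        ]
    )


def _stage(name: str, n_in: int, n_out: int, t0: float) -> dict[str, int]:
    logger.info("stage %s: in=%d out=%d elapsed=%.2fs", name, n_in, n_out, time.time() - t0)
    return {"input": n_in, "output": n_out}


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Execute the full cascade and write every stage artifact to disk."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, dict[str, int]] = {}

    # load
    t0 = time.time()
    genotypes = read_genotypes(cfg.genotypes_path, cfg.sample_sheet_path)
    annotations = read_annotations(cfg.annotations_path)
    counts["load"] = _stage("load", len(genotypes.variant_ids), len(genotypes.variant_ids), t0)

    # rare-damaging filter
    t0 = time.time()
    filt_gt, filt_ann = filter_rare_damaging(genotypes, annotations, cfg.filter_cfg)
    write_annotations(filt_ann, out / "filtered_annotations.tsv")
    write_matrix(filt_gt, out / "filtered_genotypes.tsv")
    counts["rare_filter"] = _stage(
        "rare_filter", len(genotypes.variant_ids), len(filt_gt.variant_ids), t0
    )

    # per-variant association
    t0 = time.time()
    if filt_gt.variant_ids:
        assoc = variant_association(filt_gt, cfg.association_mode)
    else:
        logger.warning("no variants survive the rare-damaging filter; downstream stages empty")
        assoc = []
    assoc_df = _assoc_frame(assoc)
    assoc_df.to_csv(out / "variant_association.tsv", sep="\t", index=False)
    pd.DataFrame(
        manhattan_points(assoc), columns=["position", "unit_id", "neglog10_p"]
    ).to_csv(out / "manhattan.tsv", sep="\t", index=False)
    sig_variants = [r for r in assoc if r.p < cfg.association_alpha]
    counts["association"] = _stage("association", len(assoc), len(sig_variants), t0)

    # gene-level burden
    t0 = time.time()
    if filt_gt.variant_ids:
        collapsed = collapse_carriers(filt_gt, filt_ann)
        burden_results = burden_test(collapsed, cfg.burden_criteria)
    else:
        burden_results = []
    _burden_frame(burden_results).to_csv(out / "burden.tsv", sep="\t", index=False)
    burden_pass = [r.gene for r in burden_results if r.passes]
    counts["burden"] = _stage("burden", len(burden_results), len(burden_pass), t0)

    # candidate union feeding enrichment: genes of Fisher-significant
    # variants plus burden-significant genes
    gene_of = {r.variant_id: r.gene for r in filt_ann}
    fisher_genes = {gene_of[r.unit_id] for r in sig_variants}
    burden_sig = {
        r.gene for r in burden_results if r.p < cfg.burden_alpha or r.q < cfg.burden_alpha
    }
    candidates = sorted(fisher_genes | burden_sig)

    # over-representation
    t0 = time.time()
    collection = read_gmt(cfg.gmt_path)
    enrich = run_ora(candidates, collection, cfg.ora_alpha) if candidates else []
    _enrich_frame(enrich).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    if cfg.selected_terms is not None:
        selected = [t for t in cfg.selected_terms if t in {r.term_id for r in enrich}]
    else:
        selected = significant_terms(enrich, cfg.ora_alpha)
    pathway_genes = (
        select_pathway_genes(enrich, collection, candidates, selected) if selected else []
    )
    counts["enrichment"] = _stage("enrichment", len(candidates), len(pathway_genes), t0)

    # network prioritization
    t0 = time.time()
    known_lists = {name: read_gene_list(p) for name, p in cfg.known_list_paths.items()}
    net = InteractionNetwork.from_edges(read_edge_list(cfg.edges_path), known_lists)
    if pathway_genes:
        scores = score_connectivity(net, pathway_genes, cfg.network_method)
        if cfg.network_k is None and cfg.network_min_score is None:
            raise ValueError("network stage requires network_k or network_min_score")
        net_genes = prioritize_by_network(scores, cfg.network_k, cfg.network_min_score)
    else:
        scores, net_genes = [], []
    pd.DataFrame(
        [
            {
                "gene": s.gene,
                **{f"n_{k}_neighbors": v for k, v in sorted(s.neighbor_counts.items())},
                "total_degree": s.total_degree,
                "combined": s.combined,
            }
            for s in scores
        ]
    ).to_csv(out / "network_scores.tsv", sep="\t", index=False)
    counts["network"] = _stage("network", len(pathway_genes), len(net_genes), t0)

    # expression prioritization
    t0 = time.time()
    expr = read_expression(cfg.expression_path)
    if net_genes:
        final_genes, summary = expression_priority(
            expr, net_genes, cfg.expression_rule, cfg.expression_threshold
        )
    else:
        final_genes, summary = [], pd.DataFrame()
    summary.to_csv(out / "expression_summary.tsv", sep="\t")
    pd.DataFrame({"gene": final_genes}).to_csv(out / "final_genes.tsv", sep="\t", index=False)
    counts["expression"] = _stage("expression", len(net_genes), len(final_genes), t0)

    report = PipelineReport(
        stage_counts=counts,
        fisher_significant_variants=_assoc_frame(sig_variants).to_dict("records"),
        burden_results=_burden_frame(burden_results).to_dict("records"),
        enrichment_results=_enrich_frame(enrich).to_dict("records"),
        selected_terms=selected,
        pathway_genes=pathway_genes,
        network_scores=[
            {
                "gene": s.gene,
                "neighbor_counts": dict(sorted(s.neighbor_counts.items())),
                "total_degree": s.total_degree,
                "combined": s.combined,
            }
            for s in scores
        ],
        network_prioritized=net_genes,
        final_genes=final_genes,
        provenance={"config": cfg.to_dict(), "version": __version__, "seed": cfg.seed},
    )
    (out / "report.json").write_text(report.to_json())
    return report


def write_demo_inputs(
    cohort: CohortGenotypes,
    annotations: Sequence[VariantRecord],
    resources,
    input_dir: Path,
) -> dict[str, Any]:
    """Write a simulated cohort + resources as the pipeline's input files."""
    from .cohort_io import write_sample_sheet, write_vcf
    from .enrichment import write_gmt
    from .expression import write_expression
    from .network import write_edge_list

    input_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes_path": str(input_dir / "cohort.vcf"),
        "sample_sheet_path": str(input_dir / "samples.tsv"),
        "annotations_path": str(input_dir / "annotations.tsv"),
        "gmt_path": str(input_dir / "gene_sets.gmt"),
        "edges_path": str(input_dir / "interactions.tsv"),
        "expression_path": str(input_dir / "expression.tsv"),
    }
    write_vcf(cohort, annotations, paths["genotypes_path"])
    write_sample_sheet(cohort, paths["sample_sheet_path"])
    write_annotations(annotations, paths["annotations_path"])
    write_gmt(resources.gene_sets, paths["gmt_path"])
    write_edge_list(resources.edges, paths["edges_path"])
    write_expression(resources.expression, paths["expression_path"])
    known_paths = {}
    for name, genes in sorted(resources.known_lists.items()):
        p = input_dir / f"known_{name}.txt"
        p.write_text("\n".join(sorted(genes)) + "\n")
        known_paths[name] = str(p)
    paths["known_list_paths"] = known_paths
    return paths


def demo(seed: int, output_dir: str | Path, network_k: int = 11) -> dict[str, Any]:
    """Simulate a cohort with planted risk genes, run the cascade, and
    report recovery confusion counts (planted vs reported).

    A planted gene is 'eligible' when its realized signal can satisfy the
    burden criteria: best-variant case hits at or above the criteria
    minimum and control carriers within the allowed maximum.
    """
    from .simulate import SimulationConfig, generate_cohort, generate_resources

    out = Path(output_dir)
    sim_cfg = SimulationConfig(seed=seed)
    cohort, annotations, truth = generate_cohort(sim_cfg)
    resources = generate_resources(sim_cfg, truth)
    paths = write_demo_inputs(cohort, annotations, resources, out / "inputs")
    cfg = PipelineConfig(
        output_dir=str(out / "results"),
        selected_terms=[resources.cardiac_term_id],
        network_k=network_k,
        seed=seed,
        **paths,
    )
    report = run_pipeline(cfg)
    criteria = cfg.burden_criteria
    eligible = [
        g
        for g in truth.planted_genes
        if truth.best_variant_case_hits[g] >= criteria.min_case_hits
        and truth.control_carriers[g] <= criteria.max_control_carriers
    ]
    final = set(report.final_genes)
    planted = set(truth.planted_genes)
    confusion = {
        "planted": sorted(planted),
        "eligible": sorted(eligible),
        "recovered": sorted(planted & final),
        "eligible_recovered": sorted(set(eligible) & final),
        "missed_eligible": sorted(set(eligible) - final),
        "false_positives": sorted(final - planted),
        "final_genes": sorted(final),
    }
    (out / "confusion.json").write_text(json.dumps(confusion, indent=2, sort_keys=True))
    return {"report": report, "confusion": confusion, "truth": truth}
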