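"""End-to-end orchestration: counts -> monotone genes -> TO-GCN -> levels
-> enrichment -> regulatory subnetwork, with every intermediate written as
a TSV when an output directory is given."""
from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import io as swio
from .config import RunConfig
from .enrichment import hypergeom_enrich, level_gene_sets
from .mfselector import monotone_results, select_monotone
from .preprocess import (
    batch_adjust,
    filter_zero_genes,
    normalize,
    stage_profiles,
    tmm_factors,
)
from .regnet import annotate_edges, key_gene_network
from .togcn import assign_levels, build_gcn, choose_seed, pcc_matrix, robustness
from .types import (
    CountMatrix,
    CoexpressionNetwork,
    GeneAnnotation,
    GeneSetCollection,
    LevelAssignment,
    LevelGeneSets,
    NormalizedMatrix,
    RegulatoryTable,
    StageProfiles,
)

logger = logging.getLogger("stagewise")


@dataclass
class PipelineResult:
    normalized: NormalizedMatrix
    profiles: StageProfiles
    results: pd.DataFrame
    selected: dict[str, list[str]]
    network: CoexpressionNetwork
    seed_gene: str
    assignment: LevelAssignment
    robustness: pd.DataFrame
    level_sets: LevelGeneSets
    enrichment: pd.DataFrame
    annotated: nx.Graph
    key_network: nx.Graph | None = None
    tables: dict[str, str] = field(default_factory=dict)


def preprocess_counts(cm: CountMatrix, cfg: RunConfig) -> NormalizedMatrix:
    """Zero filter -> TMM -> log2 CPM -> reference-batch adjustment."""
    cm = filter_zero_genes(cm)
    factors = tmm_factors(cm)
    nm = normalize(cm, factors)
    if len(cm.design.batches) > 1:
        nm = batch_adjust(nm, cfg.reference_batch)
    else:
        logger.info("preprocess: single batch, skipping batch adjustment")
    return nm


def run_pipeline(
    cm: CountMatrix,
    annotation: GeneAnnotation,
    cfg: RunConfig,
    trr: RegulatoryTable | None = None,
    gene_sets: GeneSetCollection | None = None,
    key_genes: list[str] | None = None,
    key_set: str | None = None,
    key_direction: str = "ascending",
    out_dir: str | None = None,
) -> PipelineResult:
    """Run every stage on a count matrix.

    ``key_genes`` (or ``key_set``, a gene-set name whose monotone members in
    ``key_direction`` become the key genes) drives the regulatory
    subnetwork; both optional.
    """
    nm = preprocess_counts(cm, cfg)
    profiles = stage_profiles(nm)
    results = monotone_results(nm, B=cfg.permutations, seed=cfg.seed)
    selected = select_monotone(results, de_max=cfg.de_max, q_max=cfg.q_max)

    tf_genes = {g for g in nm.gene_ids if annotation.is_tf(g)}
    tf_profiles = StageProfiles(profile=profiles.profile.loc[sorted(tf_genes)])
    pcc = pcc_matrix(tf_profiles)
    network = build_gcn(pcc, cutoff=cfg.pcc_cutoff)
    seed_gene = choose_seed(results, tf_genes)
    assignment = assign_levels(network, seed_gene)
    robust = robustness(
        network, assignment, results[results["gene"].isin(tf_genes)], pcc,
        pcc_min=cfg.robustness_pcc_min, de_max=cfg.de_max,
    )

    lsets = level_gene_sets(assignment, profiles, annotation, cfg.pcc_cutoff)
    if gene_sets is not None and len(gene_sets):
        enr = hypergeom_enrich(
            lsets, gene_sets, set(nm.gene_ids),
            fdr_max=cfg.fdr_max, family=cfg.enrichment_family,
        )
    else:
        enr = pd.DataFrame()

    annotated = annotate_edges(network, trr) if trr is not None else network.graph
    key_net = None
    if trr is not None:
        if key_genes is None and key_set is not None and gene_sets is not None:
            members = gene_sets.members(key_set)
            key_genes = [g for g in selected[key_direction] if g in members]
            logger.info(
                "key genes: %d %s monotone members of set %r",
                len(key_genes), key_direction, key_set,
            )
        if key_genes:
            key_net = key_gene_network(
                [g for g in key_genes if g in nm.gene_ids], trr, profiles, cfg.pcc_cutoff
            )

    result = PipelineResult(
        normalized=nm, profiles=profiles, results=results, selected=selected,
        network=network, seed_gene=seed_gene, assignment=assignment,
        robustness=robust, level_sets=lsets, enrichment=enr, annotated=annotated,
        key_network=key_net,
    )
    if out_dir is not None:
        result.tables = write_outputs(result, out_dir, cfg)
    return result


def write_outputs(res: PipelineResult, out_dir: str, cfg: RunConfig) -> dict[str, str]:
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}

    def _p(name: str) -> str:
        return os.path.join(out_dir, name)

    norm = res.normalized.values.rename_axis("gene").reset_index()
    paths["normalized"] = swio.write_table(norm, _p("normalized.tsv"))
    prof = res.profiles.profile.rename_axis("gene")
    prof.columns = [f"stage_{c}" for c in prof.columns]
    paths["profiles"] = swio.write_table(prof.reset_index(), _p("stage_profiles.tsv"))
    mono = res.results.copy()
    sel = {(d, g) for d, genes in res.selected.items() for g in genes}
    mono["selected"] = [
        (row.direction, row.gene) in sel for row in mono.itertuples()
    ]
    paths["monotone"] = swio.write_table(mono, _p("monotone_results.tsv"))
    paths["levels"] = swio.write_level_assignment(res.assignment, _p("levels.tsv"))
    paths["robustness"] = swio.write_table(res.robustness, _p("robustness.tsv"))
    level_rows = [
        {"level": l, "gene": g, "is_tf": g in res.level_sets.tf_sets[l]}
        for l in res.level_sets.levels
        for g in sorted(res.level_sets.gene_sets[l])
    ]
    paths["level_sets"] = swio.write_table(
        pd.DataFrame(level_rows, columns=["level", "gene", "is_tf"]), _p("level_gene_sets.tsv")
    )
    if len(res.enrichment):
        paths["enrichment"] = swio.write_table(res.enrichment, _p("enrichment.tsv"))
    paths["network_nodes"], paths["network_edges"] = swio.write_network(
        res.annotated, _p("togcn_nodes.tsv"), _p("togcn_edges.tsv")
    )
    if res.key_network is not None:
        paths["key_nodes"], paths["key_edges"] = swio.write_network(
            res.key_network, _p("key_network_nodes.tsv"), _p("key_network_edges.tsv")
        )
    logger.info("write_outputs: %d tables under %s", len(paths), out_dir)
    return paths
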