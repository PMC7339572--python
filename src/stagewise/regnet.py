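"""Regulatory annotation of co-expression edges and key-gene subnetworks.

Co-expression says two genes move together; a transcriptional regulatory
relationship (TRR) table says one may drive the other.  This module labels
TF-TF co-expression edges that have database support and builds the
TF -> key-gene subnetwork around a user-supplied list of key genes
(e.g. the ascending monotone members of a contraction pathway): a TF
qualifies as an upstream regulator of a key gene only when the directed
TRR edge exists AND the pair is co-expressed at the network cutoff.
"""
from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .enrichment import cross_pcc
from .types import CoexpressionNetwork, RegulatoryTable, StageProfiles

logger = logging.getLogger("stagewise")


def _support(trr: RegulatoryTable, a: str, b: str) -> frozenset[str]:
    """Source labels supporting a or b regulating the other (either
    direction counts for an undirected TF-TF edge)."""
    return trr.sources_for(a, b) | trr.sources_for(b, a)


def annotate_edges(net: CoexpressionNetwork, trr: RegulatoryTable) -> nx.Graph:
    """Label every co-expression edge with its TRR support.

    Topology is untouched; each edge gains ``trr_supported`` and
    ``source_labels`` attributes.
    """
    g = net.graph.copy()
    n_supported = 0
    for u, v, d in g.edges(data=True):
        labels = _support(trr, u, v)
        d["trr_supported"] = bool(labels)
        d["source_labels"] = labels
        n_supported += bool(labels)
    nx.set_node_attributes(g, "tf", name="node_type")
    logger.info(
        "annotate_edges: %d / %d edges with TRR support", n_supported, g.number_of_edges()
    )
    return g


def upstream_tfs(
    key_genes: list[str],
    trr: RegulatoryTable,
    profiles: StageProfiles,
    cutoff: float,
) -> dict[str, frozenset[str]]:
    """Qualifying upstream TFs per key gene: directed TRR edge AND
    co-expression (PCC >= cutoff) are both required."""
    missing = [g for g in key_genes if g not in profiles.profile.index]
    if missing:
        raise ValueError(f"key gene(s) absent from profiles: {missing}")
    out: dict[str, frozenset[str]] = {}
    for kg in key_genes:
        regulators = sorted(trr.regulators_of(kg) & set(profiles.profile.index))
        if not regulators:
            out[kg] = frozenset()
            continue
        r = cross_pcc(profiles, regulators, [kg]).iloc[:, 0]
        out[kg] = frozenset(tf for tf in regulators if pd.notna(r[tf]) and r[tf] >= cutoff)
    return out


def key_gene_network(
    key_genes: list[str],
    trr: RegulatoryTable,
    profiles: StageProfiles,
    cutoff: float,
) -> nx.Graph:
    """TF-TF-key-gene subnetwork around the supplied key genes.

    Nodes are the key genes plus their qualifying upstream TFs.  Edges are
    the TF -> key-gene edges from :func:`upstream_tfs` (kind ``tf_key``,
    always TRR supported by construction) plus the co-expression edges
    among the included TFs (kind ``tf_tf``, annotated for TRR support).
    """
    if not key_genes:
        raise ValueError("key gene list is empty")
    up = upstream_tfs(key_genes, trr, profiles, cutoff)
    tfs = sorted(set().union(*up.values()) if up else set())
    g = nx.Graph()
    for kg in key_genes:
        g.add_node(kg, node_type="key_gene")
    for tf in tfs:
        g.add_node(tf, node_type="tf")
    for kg, regs in up.items():
        for tf in sorted(regs):
            pcc = float(cross_pcc(profiles, [tf], [kg]).iloc[0, 0])
            g.add_edge(
                tf,
                kg,
                kind="tf_key",
                pcc=pcc,
                trr_supported=True,
                source_labels=trr.sources_for(tf, kg),
            )
    if len(tfs) >= 2:
        C = cross_pcc(profiles, tfs, tfs)
        for i, a in enumerate(tfs):
            for b in tfs[i + 1 :]:
                r = C.loc[a, b]
                if pd.notna(r) and r >= cutoff:
                    labels = _support(trr, a, b)
                    g.add_edge(
                        a,
                        b,
                        kind="tf_tf",
                        pcc=float(r),
                        trr_supported=bool(labels),
                        source_labels=labels,
                    )
    logger.info(
        "key_gene_network: %d key genes, %d TFs, %d edges",
        len(key_genes),
        len(tfs),
        g.number_of_edges(),
    )
    return g
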