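"""Time-ordered gene co-expression network (TO-GCN) construction.

TF-TF Pearson correlations over stage-mean profiles are thresholded at a
positive cutoff (default 0.91) to form an undirected co-expression network.
The TF with the strongest monotonic descending pattern (minimal DE) seeds a
breadth-first search; a node's level is its BFS distance from the seed plus
one and is read as expression time order.  Stability of the ordering is
probed by re-seeding from every strongly co-expressed (PCC > 0.99) monotone
TF and comparing level assignments by Spearman rank correlation.
"""
from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .types import CoexpressionNetwork, LevelAssignment, StageProfiles

logger = logging.getLogger("stagewise")


def pcc_matrix(profiles: StageProfiles) -> pd.DataFrame:
    """Pearson correlation of every gene pair over the T stage means.

    Genes with constant profiles have undefined PCC: their rows/columns are
    NaN (flagged, excluded from any edge) except the unit diagonal.
    """
    if profiles.n_stages < 3:
        raise ValueError("PCC over stage profiles requires T >= 3 stages")
    X = profiles.profile.to_numpy()
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1)
    constant = norm == 0
    Z = Xc / np.where(constant, 1.0, norm)[:, None]
    C = np.clip(Z @ Z.T, -1.0, 1.0)
    C[constant, :] = np.nan
    C[:, constant] = np.nan
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=profiles.gene_ids, columns=profiles.gene_ids)


def build_gcn(pcc: pd.DataFrame, cutoff: float = 0.91) -> CoexpressionNetwork:
    """Keep every gene pair with PCC >= cutoff as an undirected edge.

    Isolated genes stay in the node set; negative and sub-cutoff
    correlations contribute no edge.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    genes = list(pcc.index)
    C = pcc.to_numpy()
    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = np.nan_to_num(C[iu, ju], nan=-np.inf) >= cutoff
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(genes[i], genes[j], pcc=float(C[i, j]))
    net = CoexpressionNetwork(graph=g, cutoff=cutoff)
    logger.info(
        "build_gcn: %d nodes, %d edges at PCC >= %.2f", len(genes), net.n_edges, cutoff
    )
    return net


def choose_seed(results: pd.DataFrame, tf_genes: set[str] | frozenset[str]) -> str:
    """The descending TF with minimal DE; ties broken by smaller p-value,
    then lexicographically smaller gene id."""
    sub = results[
        (results["direction"] == "descending") & results["gene"].isin(tf_genes)
    ]
    if sub.empty:
        raise ValueError(
            "no descending TF available to seed the network; "
            "supply a seed gene explicitly"
        )
    sub = sub.sort_values(["DE", "p_value", "gene"], kind="stable")
    seed = str(sub.iloc[0]["gene"])
    logger.info(
        "choose_seed: %s (DE=%d, p=%.4g)", seed, sub.iloc[0]["DE"], sub.iloc[0]["p_value"]
    )
    return seed


def assign_levels(net: CoexpressionNetwork, seed: str) -> LevelAssignment:
    """BFS leveling: level(v) = shortest-path distance from the seed + 1.

    Nodes outside the seed's connected component are reported as
    unreachable, never silently dropped.
    """
    if seed not in net.graph:
        raise ValueError(f"seed {seed!r} is not a node of the network")
    dist = nx.single_source_shortest_path_length(net.graph, seed)
    levels = {g: d + 1 for g, d in dist.items()}
    unreachable = frozenset(set(net.graph.nodes) - set(levels))
    if unreachable:
        logger.warning(
            "assign_levels: %d TF(s) unreachable from seed %s", len(unreachable), seed
        )
    logger.info(
        "assign_levels: seed=%s, %d levels over %d reachable TFs",
        seed,
        max(levels.values()),
        len(levels),
    )
    return LevelAssignment(seed=seed, levels=levels, unreachable=unreachable)


def level_spearman(a: LevelAssignment, b: LevelAssignment) -> tuple[float, int]:
    """Spearman rank correlation of two level assignments over their shared
    reachable nodes; returns (rho, n_shared)."""
    shared = sorted(set(a.levels) & set(b.levels))
    if len(shared) < 2:
        return float("nan"), len(shared)
    la = [a.levels[g] for g in shared]
    lb = [b.levels[g] for g in shared]
    if len(set(la)) == 1 or len(set(lb)) == 1:
        # a constant assignment has no rank ordering; call it undefined
        return float("nan"), len(shared)
    rho = spearmanr(la, lb).statistic
    return float(rho), len(shared)


def robustness(
    net: CoexpressionNetwork,
    primary: LevelAssignment,
    results: pd.DataFrame,
    pcc: pd.DataFrame,
    pcc_min: float = 0.99,
    de_max: int = 4,
) -> pd.DataFrame:
    """Re-seed the BFS from every monotone TF strongly co-expressed with the
    primary seed and compare level orders.

    Alternative seeds are TFs with DE <= de_max (either direction) and
    PCC(primary seed, TF) > pcc_min.  For each, the level assignment is
    rebuilt and summarized by Spearman rank correlation with the primary
    assignment over shared reachable nodes.  An empty report (no qualifying
    seed) is logged, not an error.
    """
    seed = primary.seed
    candidates = set(results.loc[results["DE"] <= de_max, "gene"]) & set(net.graph.nodes)
    candidates.discard(seed)
    rows = []
    for alt in sorted(candidates):
        if alt not in pcc.index or seed not in pcc.index:
            continue
        r = pcc.loc[seed, alt]
        if not (pd.notna(r) and r > pcc_min):
            continue
        assignment = assign_levels(net, alt)
        rho, n_shared = level_spearman(primary, assignment)
        rows.append(
            {
                "alt_seed": alt,
                "pcc_with_primary_seed": float(r),
                "n_levels": assignment.n_levels,
                "n_shared": n_shared,
                "spearman_vs_primary": rho,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "alt_seed",
            "pcc_with_primary_seed",
            "n_levels",
            "n_shared",
            "spearman_vs_primary",
        ],
    )
    if df.empty:
        logger.info("robustness: no alternative seed with PCC > %.2f", pcc_min)
    else:
        logger.info(
            "robustness: %d alternative seeds, Spearman in [%.3f, %.3f]",
            len(df),
            df["spearman_vs_primary"].min(),
            df["spearman_vs_primary"].max(),
        )
    return df
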