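"""Per-level gene sets and hypergeometric gene-set enrichment with BH FDR.

Each network level collects its TFs plus every non-TF gene co-expressed
(PCC >= cutoff) with at least one TF at that level; because a non-TF gene
can clear the cutoff against TFs at several levels, neighbouring level sets
overlap.  Each (level, pathway) pair is then tested with the upper-tail
hypergeometric against the background of all expressed genes.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .types import (
    GeneAnnotation,
    GeneSetCollection,
    LevelAssignment,
    LevelGeneSets,
    StageProfiles,
)

logger = logging.getLogger("stagewise")


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit norm; constant rows flagged."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1)
    constant = norm == 0
    Z = np.divide(Xc, np.where(constant, 1.0, norm)[:, None])
    return Z, constant


def cross_pcc(profiles: StageProfiles, rows: list[str], cols: list[str]) -> pd.DataFrame:
    """Pearson correlation between two gene lists over stage-mean profiles.

    Genes with constant profiles have undefined PCC and get NaN.
    """
    P = profiles.profile
    Zr, cr = _standardize_rows(P.loc[rows].to_numpy())
    Zc, cc = _standardize_rows(P.loc[cols].to_numpy())
    C = Zr @ Zc.T
    C[cr, :] = np.nan
    C[:, cc] = np.nan
    return pd.DataFrame(np.clip(C, -1.0, 1.0), index=rows, columns=cols)


def level_gene_sets(
    assignment: LevelAssignment,
    profiles: StageProfiles,
    annotation: GeneAnnotation,
    cutoff: float,
) -> LevelGeneSets:
    """Attach non-TF genes to each level of the time-ordered network.

    A non-TF gene joins level l when its PCC with at least one TF assigned
    to l is >= cutoff; it may therefore join several levels.
    """
    tf_sets = {
        l: assignment.at_level(l) for l in range(1, assignment.n_levels + 1)
    }
    non_tf = [g for g in profiles.gene_ids if not annotation.is_tf(g)]
    leveled_tfs = sorted(assignment.levels)
    gene_sets: dict[int, frozenset[str]] = {}
    if non_tf and leveled_tfs:
        C = cross_pcc(profiles, non_tf, leveled_tfs).to_numpy()
        non_tf_arr = np.array(non_tf)
        import warnings

        for l, tfs in tf_sets.items():
            idx = [leveled_tfs.index(t) for t in sorted(tfs)]
            if not idx:
                gene_sets[l] = frozenset()
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
                best = np.nanmax(C[:, idx], axis=1)
            hit = best >= cutoff  # NaN compares False: constant profiles excluded
            gene_sets[l] = frozenset(tfs) | frozenset(non_tf_arr[hit])
    else:
        gene_sets = {l: frozenset(tfs) for l, tfs in tf_sets.items()}
    logger.info(
        "level_gene_sets: %d levels, set sizes %s",
        len(gene_sets),
        [len(gene_sets[l]) for l in sorted(gene_sets)],
    )
    return LevelGeneSets(tf_sets=tf_sets, gene_sets=gene_sets, cutoff=cutoff)


def hypergeom_enrich(
    level_sets: LevelGeneSets,
    collection: GeneSetCollection,
    background: set[str] | frozenset[str],
    fdr_max: float = 0.05,
    family: str = "global",
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every pathway at every level.

    For level set of size n, pathway of size K (after intersecting with the
    background of N expressed genes) and overlap k, p = P(X >= k) with
    X ~ Hypergeom(N, K, n).  BH is applied across all (level, pathway)
    tests jointly (``family="global"``) or within each level
    (``family="per_level"``).
    """
    if not background:
        raise ValueError("background gene universe is empty")
    if family not in ("global", "per_level"):
        raise ValueError("family must be 'global' or 'per_level'")
    bg = frozenset(background)
    N = len(bg)
    rows = []
    for l in level_sets.levels:
        level_genes = level_sets.gene_sets[l] & bg
        n = len(level_genes)
        for name in collection.names:
            members = collection.members(name) & bg
            K = len(members)
            k = len(level_genes & members)
            p = float(hypergeom.sf(k - 1, N, K, n))
            rows.append(
                {
                    "level": l,
                    "set_name": name,
                    "overlap": k,
                    "set_size": K,
                    "level_set_size": n,
                    "background": N,
                    "p_value": min(p, 1.0),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "level",
            "set_name",
            "overlap",
            "set_size",
            "level_set_size",
            "background",
            "p_value",
        ],
    )
    if len(df):
        if family == "global":
            df["fdr"] = bh_fdr(df["p_value"].to_numpy())
        else:
            df["fdr"] = np.nan
            for l in df["level"].unique():
                mask = df["level"] == l
                df.loc[mask, "fdr"] = bh_fdr(df.loc[mask, "p_value"].to_numpy())
        df["enriched"] = df["fdr"] < fdr_max
    else:
        df["fdr"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    logger.info(
        "hypergeom_enrich: %d tests, %d enriched at FDR<%.2f (%s family)",
        len(df),
        int(df["enriched"].sum()) if len(df) else 0,
        fdr_max,
        family,
    )
    return df
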