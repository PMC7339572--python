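"""Count filtering, TMM normalization, batch adjustment, stage profiles.

The normalization chain is: drop genes with any zero count, compute TMM
(trimmed mean of M-values) scale factors, convert to log2 counts-per-million
with a 0.5 pseudocount, adjust batches onto a declared reference batch, and
summarize each gene as its per-stage mean profile.  Everything here is
deterministic: identical inputs give bit-identical outputs.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import CountMatrix, NormalizedMatrix, StageProfiles

logger = logging.getLogger("stagewise")

PSEUDOCOUNT = 0.5
CPM_SCALE = 1e6

# canonical TMM trim fractions: 30% of M-values and 5% of A-values from each tail
TRIM_M = 0.30
TRIM_A = 0.05


def filter_zero_genes(cm: CountMatrix) -> CountMatrix:
    """Keep only genes with strictly positive counts in every sample."""
    keep = (cm.counts.to_numpy() > 0).all(axis=1)
    out = CountMatrix(counts=cm.counts.loc[keep], design=cm.design)
    logger.info(
        "filter_zero_genes: kept %d / %d genes (no zero count in any sample)",
        out.n_genes,
        cm.n_genes,
    )
    return out


def _choose_reference(counts: np.ndarray) -> int:
    """Reference sample: upper-quartile (of count fractions) closest to the
    mean upper-quartile across samples."""
    lib = counts.sum(axis=0).astype(float)
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None) -> pd.Series:
    """TMM scale factors, one per sample, geometric mean rescaled to 1.

    For each sample the factor is 2 to the weighted trimmed mean of per-gene
    log2 count-fraction ratios (M-values) against the reference sample.  The
    top/bottom 30% of M-values and top/bottom 5% of A-values are trimmed;
    weights are inverse asymptotic (delta-method binomial) variances.
    Requires a zero-free count matrix (see :func:`filter_zero_genes`).
    """
    counts = cm.counts.to_numpy().astype(float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = cm.counts.columns[np.argwhere(lib == 0)[0][0]]
        raise ValueError(f"sample {bad!r} has zero library size")
    if ref_sample is None:
        ref = _choose_reference(counts)
    else:
        ref = list(cm.counts.columns).index(ref_sample)

    factors = np.ones(counts.shape[1])
    pref = counts[:, ref] / lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        pj = counts[:, j] / lib[j]
        m = np.log2(pj / pref)
        a = 0.5 * np.log2(pj * pref)
        w = 1.0 / (
            (lib[j] - counts[:, j]) / (lib[j] * counts[:, j])
            + (lib[ref] - counts[:, ref]) / (lib[ref] * counts[:, ref])
        )
        n = m.size
        rank_m = m.argsort().argsort()
        rank_a = a.argsort().argsort()
        lo_m, hi_m = np.floor(n * TRIM_M), n - np.floor(n * TRIM_M)
        lo_a, hi_a = np.floor(n * TRIM_A), n - np.floor(n * TRIM_A)
        keep = (rank_m >= lo_m) & (rank_m < hi_m) & (rank_a >= lo_a) & (rank_a < hi_a)
        if keep.any():
            factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    logger.info(
        "tmm_factors: reference=%s, factors in [%.4f, %.4f]",
        cm.counts.columns[ref],
        factors.min(),
        factors.max(),
    )
    return pd.Series(factors, index=cm.counts.columns, name="tmm_factor")


def normalize(cm: CountMatrix, factors: pd.Series) -> NormalizedMatrix:
    """log2 CPM with pseudocount, using TMM-scaled effective library sizes.

    value(g, s) = log2( (count(g,s) + 0.5) / (lib(s) * factor(s)) * 1e6 )
    """
    counts = cm.counts.to_numpy().astype(float)
    lib = counts.sum(axis=0)
    eff = lib * factors.loc[cm.counts.columns].to_numpy()
    values = np.log2((counts + PSEUDOCOUNT) / eff * CPM_SCALE)
    df = pd.DataFrame(values, index=cm.counts.index, columns=cm.counts.columns)
    return NormalizedMatrix(values=df, design=cm.design)


def batch_adjust(nm: NormalizedMatrix, reference_batch: str) -> NormalizedMatrix:
    """Location/scale batch adjustment onto a reference batch.

    Per gene: stage (group) means are estimated from the reference batch;
    every other batch's residuals around those stage means are shifted and
    rescaled to match the reference batch's residual mean and standard
    deviation.  Reference-batch samples pass through unchanged, which makes
    the operation exactly idempotent.  This is a deliberate simplification
    of empirical-Bayes batch correction: downstream statistics only need
    batch-free stage profiles, not shrunken per-gene estimates.
    """
    design = nm.design
    batches = design.batches
    if reference_batch not in batches:
        raise ValueError(f"reference batch {reference_batch!r} not present in design")
    if len(batches) < 2:
        raise ValueError("batch_adjust requires at least 2 batches")
    batch_arr = np.asarray(design.batch_id)
    stages = design.stages
    for b in batches:
        in_b = batch_arr == b
        if in_b.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 samples")
        if len(set(stages[in_b])) == 1:
            raise ValueError(f"batch {b!r} is confounded with a single stage")
    ref_mask = batch_arr == reference_batch
    ref_stages = set(stages[ref_mask])
    missing = sorted(set(stages) - ref_stages)
    if missing:
        raise ValueError(
            f"reference batch {reference_batch!r} has no samples at stage(s) {missing}"
        )

    X = nm.values.to_numpy().copy()
    T = design.n_stages
    # stage means from the reference batch only (genes x T)
    stage_means = np.empty((X.shape[0], T))
    for t in range(1, T + 1):
        stage_means[:, t - 1] = X[:, ref_mask & (stages == t)].mean(axis=1)
    resid = X - stage_means[:, stages - 1]
    ref_resid = resid[:, ref_mask]
    ref_loc = ref_resid.mean(axis=1)
    ref_scale = ref_resid.std(axis=1, ddof=1)
    for b in batches:
        if b == reference_batch:
            continue
        mask = batch_arr == b
        rb = resid[:, mask]
        loc = rb.mean(axis=1)
        scale = rb.std(axis=1, ddof=1)
        # genes with degenerate spread in either batch: shift only
        ratio = np.where((scale > 0) & (ref_scale > 0), ref_scale / np.maximum(scale, 1e-300), 1.0)
        X[:, mask] = (
            stage_means[:, stages[mask] - 1]
            + (rb - loc[:, None]) * ratio[:, None]
            + ref_loc[:, None]
        )
    logger.info(
        "batch_adjust: %d batches onto reference %r", len(batches), reference_batch
    )
    return NormalizedMatrix(
        values=pd.DataFrame(X, index=nm.values.index, columns=nm.values.columns),
        design=design,
    )


def stage_profiles(nm: NormalizedMatrix) -> StageProfiles:
    """Per-gene, per-stage arithmetic mean across replicates."""
    stages = nm.design.stages
    T = nm.design.n_stages
    X = nm.values.to_numpy()
    prof = np.column_stack([X[:, stages == t].mean(axis=1) for t in range(1, T + 1)])
    df = pd.DataFrame(prof, index=nm.values.index, columns=list(range(1, T + 1)))
    return StageProfiles(profile=df)
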