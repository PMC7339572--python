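"""Monotonic feature selection by the discriminating-error (DE) statistic.

For a gene measured over T ordered stages, every ordered stage split k
(stages <= k vs stages > k, k = 1..T-1) is scored by the smallest number of
samples a single expression threshold misclassifies; DE is the sum of these
per-split errors.  DE = 0 means one threshold separates early from late
samples perfectly at every split — a perfectly monotone gene.  Significance
comes from permuting stage labels across samples; q-values are
Benjamini-Hochberg within each direction.

DE depends on the data only through value ranks, so it is invariant under
any strictly increasing transform, and DE(x, descending) equals
DE(-x, ascending).
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .enrichment import bh_fdr
from .types import NormalizedMatrix, SampleDesign

logger = logging.getLogger("stagewise")

DIRECTIONS = ("descending", "ascending")


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def de_statistic_matrix(
    values: np.ndarray, stages: np.ndarray, direction: str
) -> tuple[np.ndarray, np.ndarray]:
    """DE and per-split errors for every row of ``values`` (genes x samples).

    For a descending gene, "correct" at split k means early samples sit at or
    above the threshold and late samples below it; the threshold ranges over
    -inf, midpoints between consecutive distinct values, and +inf.  The
    ascending case is the mirror image, computed on negated values.

    Returns ``(de, per_split)`` with shapes (G,) and (G, T-1).
    """
    _check_direction(direction)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if direction == "ascending":
        values = -values
    stages = np.asarray(stages, dtype=np.int64)
    T = int(stages.max())
    if T < 2:
        raise ValueError("DE requires at least 2 stages")
    G, n = values.shape
    order = np.argsort(values, axis=1, kind="stable")
    vs = np.take_along_axis(values, order, axis=1)
    st = np.take_along_axis(np.broadcast_to(stages, (G, n)), order, axis=1)
    # a cut between sorted positions c-1 and c is admissible only where the
    # values differ (otherwise no threshold realizes it)
    valid = vs[:, :-1] < vs[:, 1:]
    per_split = np.empty((G, T - 1), dtype=np.int64)
    for k in range(1, T):
        # sweeping the threshold upward, an early sample crossed below it
        # becomes an error (+1) and a late sample a success (-1)
        delta = np.where(st <= k, 1, -1)
        csum = np.cumsum(delta, axis=1)
        n_late = int(np.sum(stages > k))
        err = n_late + csum  # errors with the cut after each sorted position
        err[:, :-1] = np.where(valid, err[:, :-1], n + 1)
        per_split[:, k - 1] = np.minimum(n_late, err.min(axis=1))  # n_late = cut at -inf
    return per_split.sum(axis=1), per_split


def de_statistic(
    values: np.ndarray, design: SampleDesign, direction: str
) -> tuple[int, list[int]]:
    """DE statistic of a single gene; see :func:`de_statistic_matrix`."""
    values = np.asarray(values, dtype=float)
    if values.shape != (design.n_samples,):
        raise ValueError("values must have one entry per design sample")
    if design.n_stages < 2:
        raise ValueError("DE requires at least 2 stages")
    de, per_split = de_statistic_matrix(values[None, :], design.stages, direction)
    return int(de[0]), [int(e) for e in per_split[0]]


def de_upper_bound(design: SampleDesign) -> int:
    """Largest attainable DE: sum over splits of min(|early|, |late|)."""
    stages = design.stages
    T = design.n_stages
    return int(
        sum(min(int(np.sum(stages <= k)), int(np.sum(stages > k))) for k in range(1, T))
    )


def permutation_pq(
    nm: NormalizedMatrix,
    direction: str,
    B: int = 100,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene DE with permutation p-values and BH q-values.

    p = (1 + #{b : DE_perm(b) <= DE_obs}) / (B + 1), where each of the B
    permutations shuffles the stage labels uniformly over all samples (the
    same label shuffles are applied to every gene).  q-values are BH over
    all genes for the given direction.
    """
    _check_direction(direction)
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    X = nm.values.to_numpy()
    stages = nm.design.stages
    de_obs, per_split = de_statistic_matrix(X, stages, direction)
    exceed = np.zeros(X.shape[0], dtype=np.int64)
    for _ in range(B):
        perm = rng.permutation(stages)
        de_perm, _ = de_statistic_matrix(X, perm, direction)
        exceed += de_perm <= de_obs
    p = (1.0 + exceed) / (B + 1.0)
    q = bh_fdr(p)
    df = pd.DataFrame(
        {
            "gene": nm.gene_ids,
            "direction": direction,
            "DE": de_obs,
            "per_split_errors": [",".join(map(str, row)) for row in per_split],
            "p_value": p,
            "q_value": q,
        }
    )
    logger.info(
        "permutation_pq[%s]: %d genes, B=%d, min DE=%d",
        direction,
        len(df),
        B,
        int(de_obs.min()) if len(df) else -1,
    )
    return df


def monotone_results(
    nm: NormalizedMatrix,
    B: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """DE/p/q for both directions, stacked into one table.

    A fresh child generator per direction keeps the two permutation nulls
    independent while reproducible from one seed.
    """
    root = np.random.default_rng(seed)
    frames = [
        permutation_pq(nm, direction, B=B, rng=np.random.default_rng(root.integers(2**31)))
        for direction in DIRECTIONS
    ]
    return pd.concat(frames, ignore_index=True)


def select_monotone(
    results: pd.DataFrame, de_max: int = 4, q_max: float | None = None
) -> dict[str, list[str]]:
    """Monotone gene lists per direction: DE <= de_max (and q <= q_max when
    given), sorted by (DE, q, gene id)."""
    out: dict[str, list[str]] = {}
    for direction in DIRECTIONS:
        sub = results[(results["direction"] == direction) & (results["DE"] <= de_max)]
        if q_max is not None:
            sub = sub[sub["q_value"] <= q_max]
        sub = sub.sort_values(["DE", "q_value", "gene"], kind="stable")
        out[direction] = list(sub["gene"])
    logger.info(
        "select_monotone: DE<=%s, q<=%s -> %d descending, %d ascending",
        de_max,
        q_max,
        len(out["descending"]),
        len(out["ascending"]),
    )
    return out
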