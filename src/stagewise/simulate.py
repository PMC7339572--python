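"""Synthetic time-course count data with planted ground truth.

The generator emulates the study design every pipeline stage is tested
against: 5 time stages, 3 biological replicates split over 2 batches,
negative-binomial counts, monotonically descending "stemness" genes,
ascending "terminal-fate" genes, and 9 TF modules whose activation is
ordered in time so that breadth-first leveling of the co-expression network
recovers the order.

Module mean profiles lie on a great-circle arc in centered log-expression
space, rotating from a descending line (module 1, the seed archetype)
through a mid-course peak to an ascending line (module 9).  The arc makes
the correlation between modules a fixed, monotone function of their
separation along the activation axis — adjacent modules cos(step) ~ 0.94,
two apart ~ 0.77 — which is what lets a PCC >= 0.91 threshold produce a
single connected chain of 9 levels over only five time points.  (A family
of Gaussian bumps cannot do this with T = 5: after mean-centering, the
correlation between neighbouring bumps collapses mid-course.)

Each module also carries non-TF target genes sharing the module profile,
and a planted TF -> target regulatory table restricted to within-module
edges.  Emitted gene sets include one set per module plus a "late_pathway"
set (targets of the last two modules) used to test per-level enrichment.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import io as swio
from .types import (
    CountMatrix,
    GeneAnnotation,
    GeneSetCollection,
    LevelAssignment,
    RegulatoryTable,
    SampleDesign,
)

__all__ = ["SimConfig", "SimData", "simulate", "evaluate_recovery", "write_simulated"]


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    T: int = 5                      # time stages
    reps_per_stage: int = 3         # biological replicates per stage
    reference_batch: str = "batch2" # replicate 1 -> batch1, the rest -> batch2
    n_descending: int = 100         # stemness-like, -delta per stage
    n_ascending: int = 100          # terminal-fate-like, +delta per stage
    n_null: int = 1800              # flat genes
    n_modules: int = 9              # time-ordered TF modules
    tfs_per_module: int = 8
    targets_per_module: int = 10
    activation_centers: tuple[float, ...] | None = None  # default: even over [1, T]
    arc_span_deg: float = 160.0     # total rotation of the module-profile arc
    delta: float = 1.0              # monotone effect size, log2 units per stage
    module_amplitude: float = 8.0   # module profile amplitude, log2 units
    # baseline keeps planted genes expressed through their low phase
    # (the emulated population is the study's post-zero-filter gene set)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.0
    library_log2_sd: float = 0.25   # log-normal library size factors
    dispersion: float = 0.1         # NB dispersion phi (var = mu + phi mu^2); 0 -> Poisson
    batch_log2_sd: float = 0.5      # gene-wise log2 offset of the non-reference batch
    trr_edges_per_module: int = 40  # planted TF -> target edges per module

    def __post_init__(self) -> None:
        if self.T < 3:
            raise ValueError("T must be >= 3")
        if min(self.reps_per_stage, self.n_modules, self.tfs_per_module) < 1:
            raise ValueError("counts parameters must be positive")
        if self.dispersion < 0 or self.delta < 0 or self.module_amplitude < 0:
            raise ValueError("effect and noise parameters must be non-negative")
        if self.activation_centers is not None:
            tau = list(self.activation_centers)
            if len(tau) != self.n_modules or any(
                b <= a for a, b in zip(tau, tau[1:])
            ):
                raise ValueError("activation centers must be strictly increasing, one per module")
        if self.trr_edges_per_module > self.tfs_per_module * self.targets_per_module:
            raise ValueError("more TRR edges requested than TF x target pairs per module")


@dataclass
class SimData:
    """A simulated data bundle plus its ground truth."""

    counts: CountMatrix
    annotation: GeneAnnotation
    trr: RegulatoryTable
    gene_sets: GeneSetCollection
    truth: pd.DataFrame  # gene, archetype, module, true_descending, true_ascending
    signals: pd.DataFrame = field(repr=False)  # noise-free log2 signal, genes x stages

    @property
    def design(self) -> SampleDesign:
        return self.counts.design


def _module_profiles(cfg: SimConfig) -> np.ndarray:
    """Unit-norm centered module profiles (n_modules x T) on the arc."""
    t = np.arange(1, cfg.T + 1, dtype=float)
    mid = (cfg.T + 1) / 2.0
    d = -(t - mid)
    d /= np.linalg.norm(d)
    b = -((t - mid) ** 2 - np.mean((t - mid) ** 2))
    b /= np.linalg.norm(b)
    tau = (
        np.asarray(cfg.activation_centers, dtype=float)
        if cfg.activation_centers is not None
        else np.linspace(1.0, cfg.T, cfg.n_modules)
    )
    theta = np.deg2rad(cfg.arc_span_deg) * (tau - tau[0]) / (tau[-1] - tau[0])
    return np.cos(theta)[:, None] * d[None, :] + np.sin(theta)[:, None] * b[None, :]


def _weak_monotone(signal: np.ndarray, tol: float = 1e-9) -> tuple[bool, bool]:
    """(descending, ascending) truth labels for a noise-free stage signal."""
    diffs = np.diff(signal)
    if np.all(np.abs(diffs) <= tol):
        return False, False  # flat: no direction
    return bool(np.all(diffs <= tol)), bool(np.all(diffs >= -tol))


def simulate(cfg: SimConfig, seed: int | None = None) -> SimData:
    """Draw a count matrix with planted truth; fully reproducible given seed."""
    rng = np.random.default_rng(seed)
    T, reps = cfg.T, cfg.reps_per_stage
    t = np.arange(1, T + 1, dtype=float)
    mid = (T + 1) / 2.0

    archetypes: list[str] = []
    modules: list[int] = []
    signals: list[np.ndarray] = []
    S = _module_profiles(cfg)
    for _ in range(cfg.n_descending):
        archetypes.append("descending"); modules.append(-1)
        signals.append(-cfg.delta * (t - mid))
    for _ in range(cfg.n_ascending):
        archetypes.append("ascending"); modules.append(-1)
        signals.append(cfg.delta * (t - mid))
    for m in range(cfg.n_modules):
        for _ in range(cfg.tfs_per_module):
            archetypes.append("module_tf"); modules.append(m + 1)
            signals.append(cfg.module_amplitude * S[m])
        for _ in range(cfg.targets_per_module):
            archetypes.append("module_target"); modules.append(m + 1)
            signals.append(cfg.module_amplitude * S[m])
    for _ in range(cfg.n_null):
        archetypes.append("null"); modules.append(-1)
        signals.append(np.zeros(T))
    n_genes = len(archetypes)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sig = np.vstack(signals)

    # sample design: replicate 1 in batch1, remaining replicates in batch2
    sample_ids, stage_idx, rep_ids, batch_ids = [], [], [], []
    for st in range(1, T + 1):
        for r in range(1, reps + 1):
            sample_ids.append(f"s{st}r{r}")
            stage_idx.append(st)
            rep_ids.append(f"r{r}")
            batch_ids.append("batch1" if r == 1 else cfg.reference_batch)
    design = SampleDesign(
        sample_ids=tuple(sample_ids),
        stage_index=tuple(stage_idx),
        replicate_id=tuple(rep_ids),
        batch_id=tuple(batch_ids),
    )

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n_genes)
    batch_offsets = rng.normal(0.0, cfg.batch_log2_sd, size=n_genes)
    lib = 2.0 ** rng.normal(0.0, cfg.library_log2_sd, size=design.n_samples)

    stages = design.stages
    nonref = np.array([b != cfg.reference_batch for b in design.batch_id])
    log2mu = (
        baseline[:, None]
        + sig[:, stages - 1]
        + np.where(nonref, batch_offsets[:, None], 0.0)
    )
    mu = (2.0 ** log2mu) * lib[None, :]
    if cfg.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    cm = CountMatrix(
        counts=pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=sample_ids),
        design=design,
    )

    arr = np.array(archetypes)
    mod_arr = np.array(modules)
    annotation = GeneAnnotation(
        tf_genes=frozenset(np.array(gene_ids)[arr == "module_tf"])
    )

    # planted within-module TF -> target regulatory edges
    trr_records: list[tuple[str, str, str]] = []
    source_pool = ("marbach", "trrust")
    for m in range(1, cfg.n_modules + 1):
        tfs = [g for g, a, mm in zip(gene_ids, arr, mod_arr) if a == "module_tf" and mm == m]
        tgs = [g for g, a, mm in zip(gene_ids, arr, mod_arr) if a == "module_target" and mm == m]
        pairs = [(tf, tg) for tf in tfs for tg in tgs]
        take = rng.choice(len(pairs), size=min(cfg.trr_edges_per_module, len(pairs)), replace=False)
        for idx in sorted(take):
            tf, tg = pairs[idx]
            trr_records.append((tf, tg, source_pool[int(rng.integers(2))]))
            if rng.random() < 0.25:  # some edges reported in both databases
                other = source_pool[1] if trr_records[-1][2] == source_pool[0] else source_pool[0]
                trr_records.append((tf, tg, other))
    trr = RegulatoryTable.from_records(trr_records)

    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for m in range(1, cfg.n_modules + 1):
        members = frozenset(
            g for g, a, mm in zip(gene_ids, arr, mod_arr)
            if a == "module_target" and mm == m
        )
        sets[f"module_{m}_targets"] = (f"targets of time module {m}", members)
    late = frozenset().union(
        *(
            sets[f"module_{m}_targets"][1]
            for m in range(max(1, cfg.n_modules - 1), cfg.n_modules + 1)
        )
    )
    sets["late_pathway"] = ("targets of the last two time modules", late)
    sets["stemness"] = (
        "planted descending genes",
        frozenset(np.array(gene_ids)[arr == "descending"]),
    )
    sets["terminal_fate"] = (
        "planted ascending genes",
        frozenset(np.array(gene_ids)[arr == "ascending"]),
    )
    gene_sets = GeneSetCollection(sets=sets)

    mono = np.array([_weak_monotone(s) for s in sig])
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "archetype": archetypes,
            "module": modules,
            "true_descending": mono[:, 0],
            "true_ascending": mono[:, 1],
            "baseline_log2": baseline,
            "batch_offset_log2": batch_offsets,
        }
    )
    signals_df = pd.DataFrame(sig, index=gene_ids, columns=list(range(1, T + 1)))
    return SimData(
        counts=cm,
        annotation=annotation,
        trr=trr,
        gene_sets=gene_sets,
        truth=truth,
        signals=signals_df,
    )


def write_simulated(data: SimData, out_dir: str) -> dict[str, str]:
    """Write the bundle in the same formats the readers consume."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "counts": os.path.join(out_dir, "counts.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "tf_list": os.path.join(out_dir, "tf_list.txt"),
        "trr": os.path.join(out_dir, "trr.tsv"),
        "gene_sets": os.path.join(out_dir, "gene_sets.gmt"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    swio.write_counts(data.counts, paths["counts"], paths["metadata"])
    swio.write_tf_list(data.annotation, paths["tf_list"])
    swio.write_regulatory_table(data.trr, paths["trr"])
    swio.write_gene_sets(data.gene_sets, paths["gene_sets"])
    data.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def evaluate_recovery(
    truth: pd.DataFrame,
    selected: dict[str, list[str]],
    assignment: LevelAssignment | None = None,
    universe: set[str] | None = None,
    key_net=None,
    trr: RegulatoryTable | None = None,
) -> dict[str, float]:
    """Score pipeline output against the planted truth.

    Recall is measured over the planted linear monotone archetypes (within
    the expressed universe when given); precision counts a selected gene as
    correct when its noise-free signal is weakly monotone in the claimed
    direction (module-edge genes are genuinely monotone by construction).
    Level recovery is the Spearman correlation between each reachable module
    TF's planted module index and its assigned level.  TRR recovery is the
    fraction of planted TF -> key-gene edges present in ``key_net`` plus the
    count of its TF -> key edges absent from the planted table.
    """
    t = truth.set_index("gene")
    metrics: dict[str, float] = {}
    for direction, flag in (("descending", "true_descending"), ("ascending", "true_ascending")):
        sel = set(selected.get(direction, []))
        planted = set(t.index[t["archetype"] == direction])
        if universe is not None:
            planted &= universe
        true_dir = set(t.index[t[flag]])
        metrics[f"recall_{direction}"] = (
            len(sel & planted) / len(planted) if planted else float("nan")
        )
        metrics[f"precision_{direction}"] = (
            len(sel & true_dir) / len(sel) if sel else float("nan")
        )
    if assignment is not None:
        tf_mask = t["archetype"] == "module_tf"
        pairs = [
            (int(t.loc[g, "module"]), assignment.levels[g])
            for g in t.index[tf_mask]
            if g in assignment.levels
        ]
        if len(pairs) >= 2:
            mods, levels = zip(*pairs)
            metrics["module_level_spearman"] = float(spearmanr(mods, levels).statistic)
            metrics["n_levels"] = float(max(assignment.levels.values()))
        metrics["n_unreachable_tfs"] = float(len(assignment.unreachable))
    if key_net is not None and trr is not None:
        key_genes = {n for n, d in key_net.nodes(data=True) if d.get("node_type") == "key_gene"}
        if universe is not None:
            key_genes &= universe
        planted_edges = {
            (a, b) for a, b, _ in trr.edges if b in key_genes and (universe is None or a in universe)
        }
        found_directed = set()
        for u, v, d in key_net.edges(data=True):
            if d.get("kind") == "tf_key":
                tf, kg = (u, v) if key_net.nodes[v].get("node_type") == "key_gene" else (v, u)
                found_directed.add((tf, kg))
        metrics["trr_edge_recall"] = (
            len(found_directed & planted_edges) / len(planted_edges)
            if planted_edges
            else float("nan")
        )
        metrics["trr_spurious_edges"] = float(
            len([e for e in found_directed if not trr.has_edge(*e)])
        )
    return metrics
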