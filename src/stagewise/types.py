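"""Core data containers shared by every pipeline stage.

The pipeline moves a gene x sample count matrix through normalization,
monotonic feature selection, co-expression network construction and
enrichment.  Each stage consumes and produces one of the small typed
containers below; all of them wrap pandas/numpy objects so that callers
can drop down to DataFrames when convenient.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "SampleDesign",
    "CountMatrix",
    "NormalizedMatrix",
    "StageProfiles",
    "GeneAnnotation",
    "GeneSetCollection",
    "RegulatoryTable",
    "CoexpressionNetwork",
    "LevelAssignment",
    "LevelGeneSets",
]


@dataclass(frozen=True)
class SampleDesign:
    """Sample metadata: one row per sample with time stage, replicate, batch.

    ``stage_index`` is the ordered stage (1..T); the analysis axis is the
    stage index, not the calendar day (the study sampled days 1, 2, 3, 5, 7
    but treats them as five ordered stages).
    """

    sample_ids: tuple[str, ...]
    stage_index: tuple[int, ...]
    replicate_id: tuple[str, ...]
    batch_id: tuple[str, ...]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.stage_index) == len(self.replicate_id) == len(self.batch_id) == n):
            raise ValueError("design fields must have equal length")
        if n == 0:
            raise ValueError("design must contain at least one sample")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in design")
        stages = sorted(set(self.stage_index))
        if stages != list(range(1, len(stages) + 1)):
            raise ValueError("stages must be contiguous from 1")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_stages(self) -> int:
        return max(self.stage_index)

    @property
    def stages(self) -> np.ndarray:
        """Stage index per sample as an int array."""
        return np.asarray(self.stage_index, dtype=np.int64)

    @property
    def batches(self) -> tuple[str, ...]:
        """Distinct batch ids in order of first appearance."""
        seen: dict[str, None] = {}
        for b in self.batch_id:
            seen.setdefault(b)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "stage": self.stage_index,
                "replicate": self.replicate_id,
                "batch": self.batch_id,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SampleDesign":
        return cls(
            sample_ids=tuple(str(s) for s in df["sample_id"]),
            stage_index=tuple(int(s) for s in df["stage"]),
            replicate_id=tuple(str(s) for s in df["replicate"]),
            batch_id=tuple(str(s) for s in df["batch"]),
        )


@dataclass(frozen=True)
class CountMatrix:
    """Raw gene x sample integer counts aligned to a :class:`SampleDesign`."""

    counts: pd.DataFrame  # genes x samples, int dtype
    design: SampleDesign

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.design.sample_ids):
            raise ValueError("count columns must match design sample ids in order")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class NormalizedMatrix:
    """log2 normalized counts-per-million (with pseudocount), genes x samples."""

    values: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.design.sample_ids):
            raise ValueError("value columns must match design sample ids in order")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("normalized values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class StageProfiles:
    """Per-gene expression profile over stages: entry (g, t) is the mean
    normalized value of gene g across the replicates of stage t."""

    profile: pd.DataFrame  # genes x stages, columns are stage indices 1..T

    @property
    def gene_ids(self) -> list[str]:
        return list(self.profile.index)

    @property
    def n_stages(self) -> int:
        return self.profile.shape[1]


@dataclass(frozen=True)
class GeneAnnotation:
    """Which genes are transcription factors; unlisted genes default to False."""

    tf_genes: frozenset[str]

    def is_tf(self, gene_id: str) -> bool:
        return gene_id in self.tf_genes

    def tf_flags(self, gene_ids: Iterable[str]) -> dict[str, bool]:
        return {g: g in self.tf_genes for g in gene_ids}


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style): name -> (description, members)."""

    sets: Mapping[str, tuple[str, frozenset[str]]]  # insertion-ordered

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class RegulatoryTable:
    """Directed TF -> target regulatory edges with a source label.

    Duplicated (tf, target, source) triples are collapsed; the same pair may
    appear under several sources.  Self-loops are kept but flagged.
    """

    edges: tuple[tuple[str, str, str], ...]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "RegulatoryTable":
        seen: dict[tuple[str, str, str], None] = {}
        for tf, tg, src in records:
            seen.setdefault((str(tf), str(tg), str(src)))
        return cls(edges=tuple(seen))

    @property
    def self_loops(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(e for e in self.edges if e[0] == e[1])

    def sources_for(self, tf: str, target: str) -> frozenset[str]:
        """Source labels supporting the directed edge tf -> target."""
        return frozenset(s for a, b, s in self.edges if a == tf and b == target)

    def has_edge(self, tf: str, target: str) -> bool:
        return any(a == tf and b == target for a, b, _ in self.edges)

    def targets_of(self, tf: str) -> frozenset[str]:
        return frozenset(b for a, b, _ in self.edges if a == tf)

    def regulators_of(self, target: str) -> frozenset[str]:
        return frozenset(a for a, b, _ in self.edges if b == target)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["tf", "target", "source"])


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Undirected TF-TF graph; every edge carries the PCC that put it there."""

    graph: nx.Graph
    cutoff: float

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError("self-edges are not allowed")
            if d["pcc"] < self.cutoff:
                raise ValueError(f"edge ({u},{v}) below cutoff")

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass(frozen=True)
class LevelAssignment:
    """Time-order levels: level = BFS distance from the seed TF, plus one."""

    seed: str
    levels: Mapping[str, int]
    unreachable: frozenset[str]

    @property
    def n_levels(self) -> int:
        return max(self.levels.values()) if self.levels else 0

    def at_level(self, level: int) -> frozenset[str]:
        return frozenset(g for g, l in self.levels.items() if l == level)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, l) for g, l in self.levels.items()]
        rows += [(g, 0) for g in sorted(self.unreachable)]
        df = pd.DataFrame(rows, columns=["gene", "level"])
        return df.sort_values(["level", "gene"]).reset_index(drop=True)


@dataclass(frozen=True)
class LevelGeneSets:
    """Per level: the TFs assigned to it plus the non-TF genes co-expressed
    (PCC >= cutoff) with at least one of those TFs.  A non-TF gene may appear
    at several levels, so neighbouring sets can overlap."""

    tf_sets: Mapping[int, frozenset[str]]
    gene_sets: Mapping[int, frozenset[str]]  # TFs + attached non-TF genes
    cutoff: float

    @property
    def levels(self) -> list[int]:
        return sorted(self.gene_sets)
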