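"""Run configuration: a flat key-value document (YAML) with CLI overrides.

Defaults mirror the study's stated settings: DE threshold 4, PCC cutoff
0.91, 100 permutations, 5 stages with 3 replicates in 2 batches.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml


@dataclass
class RunConfig:
    # study design expected in the input data
    stages: int = 5
    replicates: int = 3
    reference_batch: str = "batch2"
    # monotonic feature selection
    de_max: int = 4
    q_max: float = 0.05
    # With the plain permutation null the smallest attainable p is 1/(B+1);
    # after BH across all genes, q < q_max is only reachable when
    # 1/(B+1) * n_genes / n_monotone < q_max.  1000 permutations give the
    # q-filter real resolution; B=100 would floor q near 0.08 here.
    permutations: int = 1000
    # co-expression network
    pcc_cutoff: float = 0.91
    robustness_pcc_min: float = 0.99
    # enrichment
    fdr_max: float = 0.05
    enrichment_family: str = "global"  # "global" or "per_level"
    # reproducibility
    seed: int = 1

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **overrides: object) -> "RunConfig":
        """Return a copy with non-None overrides applied (CLI flags win)."""
        updates = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **updates)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
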