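from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stagewise import (
    CountMatrix,
    RunConfig,
    SampleDesign,
    SimConfig,
    run_pipeline,
    simulate,
)
from stagewise.simulate import evaluate_recovery


def make_design(T=5, reps=3, batches=("batch1", "batch2", "batch2")):
    """A T-stage design with `reps` replicates; replicate r sits in batches[r-1]."""
    sample_ids, stage, rep, batch = [], [], [], []
    for t in range(1, T + 1):
        for r in range(1, reps + 1):
            sample_ids.append(f"s{t}r{r}")
            stage.append(t)
            rep.append(f"r{r}")
            batch.append(batches[r - 1] if r - 1 < len(batches) else batches[-1])
    return SampleDesign(
        sample_ids=tuple(sample_ids),
        stage_index=tuple(stage),
        replicate_id=tuple(rep),
        batch_id=tuple(batch),
    )


def make_counts(arr, design, gene_ids=None):
    arr = np.asarray(arr)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=gene_ids, columns=list(design.sample_ids))
    return CountMatrix(counts=df.astype(np.int64), design=design)


@pytest.fixture(scope="session")
def design_5x1():
    """Five stages, one sample each, single batch."""
    return make_design(T=5, reps=1, batches=("batch1",))


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study: 5 stages x 3 reps in 2 batches, 9 TF
    modules, 100 descending / 100 ascending / 1800 null genes."""
    return simulate(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full pipeline output on the default synthetic data, shared across
    the end-to-end checks."""
    cfg = RunConfig(seed=1)
    return run_pipeline(
        default_sim.counts,
        default_sim.annotation,
        cfg,
        trr=default_sim.trr,
        gene_sets=default_sim.gene_sets,
        key_set="late_pathway",
        key_direction="ascending",
    )


@pytest.fixture(scope="session")
def default_metrics(default_sim, default_run):
    return evaluate_recovery(
        default_sim.truth,
        default_run.selected,
        default_run.assignment,
        universe=set(default_run.normalized.gene_ids),
        key_net=default_run.key_network,
        trr=default_sim.trr,
    )
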