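import numpy as np
import pandas as pd
import pytest

from stagewise import (
    batch_adjust,
    filter_zero_genes,
    normalize,
    stage_profiles,
    tmm_factors,
)
from stagewise.types import NormalizedMatrix

from _oracles import tmm_oracle
from conftest import make_counts, make_design


class TestFilterZeroGenes:
    def test_rules(self):
        design = make_design(T=3, reps=1, batches=("b1",))
        cm = make_counts([[5, 0, 3], [1, 1, 1], [2, 3, 4]], design)
        out = filter_zero_genes(cm)
        assert out.gene_ids == ["g1", "g2"]  # (5,0,3) removed, others kept

    def test_all_positive_unchanged_and_idempotent(self):
        design = make_design(T=3, reps=1, batches=("b1",))
        cm = make_counts([[5, 1, 3], [1, 1, 1]], design)
        once = filter_zero_genes(cm)
        pd.testing.assert_frame_equal(once.counts, cm.counts)
        twice = filter_zero_genes(once)
        pd.testing.assert_frame_equal(twice.counts, once.counts)


class TestTMM:
    def test_identical_samples_unit_factors(self):
        design = make_design(T=2, reps=1, batches=("b1",))
        cm = make_counts([[10, 10], [20, 20], [5, 5]], design)
        f = tmm_factors(cm)
        assert np.allclose(f.to_numpy(), 1.0)

    def test_scaled_sample_equal_cpm(self):
        rng = np.random.default_rng(0)
        design = make_design(T=2, reps=1, batches=("b1",))
        a = rng.integers(50, 500, size=30)
        cm = make_counts(np.column_stack([a, 2 * a]), design)
        f = tmm_factors(cm)
        counts = cm.counts.to_numpy().astype(float)
        lib = counts.sum(axis=0)
        cpm = counts / (lib * f.to_numpy()) * 1e6
        assert np.allclose(cpm[:, 0], cpm[:, 1], atol=1e-9, rtol=0)

    def test_matches_literal_oracle(self):
        rng = np.random.default_rng(7)
        design = make_design(T=3, reps=1, batches=("b1",))
        counts = rng.integers(5, 2000, size=(20, 3))
        cm = make_counts(counts, design)
        f = tmm_factors(cm, ref_sample="s1r1")
        expected = tmm_oracle(counts, ref=0)
        assert np.allclose(f.to_numpy(), expected, rtol=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(3)
        design = make_design(T=3, reps=1, batches=("b1",))
        counts = rng.integers(5, 2000, size=(40, 3))
        cm = make_counts(counts, design)
        perm = rng.permutation(40)
        cm_perm = make_counts(counts[perm], design, gene_ids=[f"g{i}" for i in perm])
        assert np.allclose(
            tmm_factors(cm, ref_sample="s1r1").to_numpy(),
            tmm_factors(cm_perm, ref_sample="s1r1").to_numpy(),
        )

    def test_zero_library_errors(self):
        design = make_design(T=2, reps=1, batches=("b1",))
        cm = make_counts([[0, 5], [0, 5]], design)
        with pytest.raises(ValueError, match="zero library size"):
            tmm_factors(cm)


class TestNormalize:
    def test_direct_arithmetic(self):
        # one gene at count 500 in a sample with library 1e6 and unit factor
        design = make_design(T=2, reps=1, batches=("b1",))
        cm = make_counts([[500, 500], [999500, 999500]], design)
        nm = normalize(cm, pd.Series([1.0, 1.0], index=cm.counts.columns))
        assert nm.values.iloc[0, 0] == pytest.approx(np.log2(500.5), abs=1e-9)

    def test_zero_count_finite(self):
        design = make_design(T=2, reps=1, batches=("b1",))
        cm = make_counts([[0, 3], [10, 10]], design)
        nm = normalize(cm, pd.Series([1.0, 1.0], index=cm.counts.columns))
        assert np.isfinite(nm.values.to_numpy()).all()

    def test_doubling_sample_invariance(self):
        rng = np.random.default_rng(1)
        design = make_design(T=2, reps=1, batches=("b1",))
        a = rng.integers(500, 5000, size=50)
        cm1 = make_counts(np.column_stack([a, a]), design)
        cm2 = make_counts(np.column_stack([a, 2 * a]), design)
        ones = pd.Series([1.0, 1.0], index=cm1.counts.columns)
        v1 = normalize(cm1, ones).values.iloc[:, 1]
        v2 = normalize(cm2, ones).values.iloc[:, 1]
        # doubled counts against a doubled library: only the pseudocount moves
        assert np.allclose(v1, v2, atol=2e-3)


def _toy_normalized(values, design):
    df = pd.DataFrame(
        values, index=[f"g{i}" for i in range(len(values))], columns=list(design.sample_ids)
    )
    return NormalizedMatrix(values=df, design=design)


class TestBatchAdjust:
    def test_single_batch_errors(self):
        design = make_design(T=3, reps=2, batches=("b1", "b1"))
        nm = _toy_normalized(np.zeros((2, 6)), design)
        with pytest.raises(ValueError, match="at least 2 batches"):
            batch_adjust(nm, "b1")

    def test_confounded_batch_errors(self):
        design = make_design(T=1, reps=4, batches=("b1", "b1", "b2", "b2"))
        nm = _toy_normalized(np.zeros((2, 4)), design)
        with pytest.raises(ValueError, match="confounded"):
            batch_adjust(nm, "b2")

    def test_planted_offset_removed(self):
        # gene = stage effect + offset delta on batch 2 (the reference):
        # batch-1 samples must shift by +delta, batch-2 stay put
        rng = np.random.default_rng(5)
        design = make_design(T=5, reps=4, batches=("b1", "b1", "b2", "b2"))
        delta = 1.7
        stage_eff = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        base = stage_eff[np.asarray(design.stage_index) - 1]
        in_b2 = np.array([b == "b2" for b in design.batch_id])
        noise = rng.normal(0, 0.05, size=(30, design.n_samples))
        vals = base[None, :] + delta * in_b2[None, :] + noise
        nm = _toy_normalized(vals, design)
        out = batch_adjust(nm, "b2").values.to_numpy()
        # reference batch untouched
        assert np.allclose(out[:, in_b2], vals[:, in_b2])
        shift = out[:, ~in_b2] - vals[:, ~in_b2]
        assert abs(shift.mean() - delta) < 0.05

    def test_zero_effect_near_identity(self):
        rng = np.random.default_rng(6)
        design = make_design(T=5, reps=4, batches=("b1", "b1", "b2", "b2"))
        vals = rng.normal(0, 1.0, size=(40, design.n_samples))
        out = batch_adjust(_toy_normalized(vals, design), "b2").values.to_numpy()
        in_b2 = np.array([b == "b2" for b in design.batch_id])
        # reference batch passes through untouched; the rest move only by
        # estimation noise, and residual batch offsets vanish exactly
        assert np.array_equal(out[:, in_b2], vals[:, in_b2])
        assert np.abs(out - vals).mean() < 0.5
        gap = out[:, ~in_b2].mean(axis=1) - out[:, in_b2].mean(axis=1)
        assert np.abs(gap).max() < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        design = make_design(T=3, reps=4, batches=("b1", "b1", "b2", "b2"))
        vals = rng.normal(0, 1.0, size=(25, design.n_samples))
        vals[:, [b == "b1" for b in design.batch_id]] += 0.8
        once = batch_adjust(_toy_normalized(vals, design), "b2")
        twice = batch_adjust(once, "b2")
        assert np.allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-8, rtol=0
        )


class TestStageProfiles:
    def test_one_sample_per_stage_identity(self):
        design = make_design(T=4, reps=1, batches=("b1",))
        vals = np.arange(8.0).reshape(2, 4)
        prof = stage_profiles(_toy_normalized(vals, design)).profile
        assert np.allclose(prof.to_numpy(), vals)

    def test_replicate_mean(self):
        design = make_design(T=1, reps=2, batches=("b1", "b1"))
        prof = stage_profiles(_toy_normalized([[4.0, 6.0]], design)).profile
        assert prof.iloc[0, 0] == pytest.approx(5.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        design = make_design(T=5, reps=3)
        vals = rng.normal(size=(20, 15))
        prof = stage_profiles(_toy_normalized(vals, design)).profile.to_numpy()
        stages = np.asarray(design.stage_index)
        for t in range(1, 6):
            expected = vals[:, stages == t].mean(axis=1)
            assert np.allclose(prof[:, t - 1], expected)
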