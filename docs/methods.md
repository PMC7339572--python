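# Methods

## Scope and data model

The pipeline analyzes a time-course bulk RNA-seq experiment summarized as
a gene × sample matrix of raw counts with per-sample metadata (ordered
time stage 1..T, replicate, batch).  The default design mirrors the
intended application: T = 5 stages, 3 biological replicates per stage
split over 2 batches (replicate 1 in batch 1, replicates 2–3 in batch 2,
which is the reference batch).  The analysis axis is always the stage
*index*; unevenly spaced sampling days are treated as ordered stages, not
as calendar time.

## Normalization chain

1. **Zero filter.**  Only genes with strictly positive counts in every
   sample are kept.  Downstream statistics (rank-based DE, Pearson
   correlation of log profiles) behave poorly for genes that switch
   between "absent" and "present", so the expressed universe is defined
   once, up front, and doubles as the enrichment background.
2. **TMM scale factors.**  Trimmed mean of M-values against a reference
   sample (the sample whose upper-quartile count fraction is closest to
   the mean upper-quartile).  Per gene: M = log2 ratio of count fractions,
   A = mean log2 abundance; the top/bottom 30% of M and top/bottom 5% of A
   are trimmed; remaining M-values are averaged with
   inverse-delta-method-variance weights
   (1/cnt − 1/lib, summed over both samples); factors are rescaled to
   geometric mean 1.  These are the cited algorithm's canonical
   parameters; the implementation is checked against a literal
   step-by-step re-derivation in the tests.
3. **log2 CPM.**  value = log2((count + 0.5) / (lib × factor) × 1e6).
   Pseudocount 0.5 and the 1e6 scale are conventional; DE is invariant to
   any strictly increasing transform, so these constants cannot change
   monotone-gene selection.
4. **Reference-batch adjustment.**  Per gene, stage (group) means are
   estimated from the reference batch only; every other batch's residuals
   around those stage means are shifted and rescaled to the reference
   batch's residual mean and standard deviation.  Reference-batch samples
   pass through unchanged, which makes the operation exactly idempotent
   and keeps stage means anchored to the reference batch.  This is a
   deliberate simplification of empirical-Bayes batch correction
   (no shrinkage across genes): the downstream statistics consume only
   batch-free stage profiles, and on the synthetic data the adjustment
   removes > 80% of the planted between-batch variance.  It requires the
   reference batch to observe every stage and ≥ 2 samples per batch;
   batches confounded with a single stage are rejected.
5. **Stage profiles.**  Per gene, the arithmetic mean of adjusted values
   across the replicates of each stage (a genes × T matrix).

## Discriminating error and permutation test

For direction *descending*, split k calls a sample "correct" when early
samples (stage ≤ k) lie at or above a threshold t and late samples below
it; e_k is the minimum error count over t ∈ {−∞, midpoints between
consecutive distinct values, +∞}, and DE = Σ e_k.  Ascending is the
mirror image, computed on negated values, which makes the duality
DE(x, descending) = DE(−x, ascending) exact.  DE is computed on
replicate-level normalized values — all samples carry errors — not on
stage means, which would cap e_k at min(k, T−k) and degrade the
permutation null.  The implementation sweeps the sorted values with a
cumulative ±1 tally (early → +1, late → −1), skipping cuts between tied
values; it is verified exactly against exhaustive threshold enumeration.

Significance: B permutations shuffle the stage labels uniformly over all
samples (the same shuffles for every gene), and
p = (1 + #{DE_perm ≤ DE_obs}) / (B + 1); q-values are BH within each
direction.  Genes with DE ≤ 4 (and optionally q ≤ 0.05) are selected,
sorted by (DE, q, gene id).

Two numerical consequences of this construction are worth stating:

- **Discreteness.**  DE is integer-valued, so null p-values are
  super-uniform; at α = 0.05 the empirical type-I rate on pure-noise
  genes is ≈ 0.035–0.045 (conservative, never anti-conservative).
- **Permutation resolution.**  The smallest attainable p is 1/(B+1).
  After BH across G genes of which a fraction φ are truly monotone,
  q < q_max is only reachable when 1/(B+1) < φ·q_max.  With B = 100,
  G ≈ 2,000 and φ ≈ 0.13 the q-floor is ≈ 0.08 and the q-filter would
  select nothing; the pipeline therefore defaults to B = 1,000
  (q-floor ≈ 0.008).  The `permutation_pq` function itself defaults to
  B = 100 for single calls; the pipeline config overrides it.

## TO-GCN construction

Pearson correlations are computed between TF stage-mean profiles (T
values per gene; replicate-level correlation is available by passing the
normalized matrix instead).  Genes with constant profiles have undefined
PCC and are flagged, never edged.  An edge is kept iff PCC ≥ cutoff
(default 0.91, the "≥" convention at the boundary); negative
co-expression is discarded.  The seed is the descending TF with minimal
DE (ties: smaller p, then lexicographic id); level(v) = BFS distance + 1.
TFs disconnected from the seed are reported as unreachable, never
silently dropped.  Raising the cutoff can only remove edges, therefore
never decreases any node's level or reachability.

**Seed robustness.**  Every TF with DE ≤ 4 and PCC > 0.99 with the
primary seed is used as an alternative seed; each rebuilt assignment is
compared to the primary by Spearman rank correlation over shared
reachable nodes.  On the default synthetic data 7 alternative seeds
qualify and all agree with the primary at ρ ≥ 0.99.  Note that exact
ρ = 1 is not expected even in ideal cases: moving the seed one step
inverts the order of the nodes behind it (on a path a–b–c–d, seeds a and
b give levels (1,2,3,4) vs (2,1,2,3), ρ ≈ 0.63), so stability is a
property of networks with broad levels, not of the BFS itself.

## Level gene sets and enrichment

A non-TF gene joins level ℓ when its PCC with at least one TF at ℓ
reaches the cutoff (the existential rule); a gene may join several —
typically neighbouring — levels.  Each (level, pathway) pair is scored by
the upper-tail hypergeometric P(X ≥ k) with N = expressed background,
K = pathway ∩ background, n = level-set size, k = overlap, and BH is
applied across all (level, pathway) tests jointly by default ("global"
family; "per_level" is available since the correct family is a judgement
call).  Records with FDR < 0.05 are flagged enriched.

## Regulatory annotation and key-gene networks

A curated TF→target table (with a source label per record, e.g. separate
database provenances) annotates the co-expression network: an undirected
TF–TF edge is "supported" when either direction appears in the table, and
the supporting source labels are attached.  For key genes — a
user-supplied list, typically the ascending DE ≤ 4 members of a pathway
of interest; the choice is curatorial, not algorithmic — an upstream TF
qualifies only under the dual gate: the directed TF→key edge exists in
the table AND PCC(TF, key) ≥ cutoff.  The resulting subnetwork contains
the key genes, their qualifying TFs, all gated TF→key edges and the
co-expression edges among the included TFs.  The table is a hard superset
constraint: no regulator can appear that the table does not license.

## Synthetic data generator

The generator emulates the study conditions so that every stage has a
no-download test surface with known truth.  Defaults: 100 descending and
100 ascending genes (linear, δ = 1 log2 unit per stage), 1,800 null
genes, and 9 TF modules (8 TFs + 10 non-TF targets each) with strictly
ordered activation centers.

**Module profiles.**  Module mean profiles lie on a great-circle arc in
centered log-expression space: s_θ = cos θ · d + sin θ · b, where d is
the unit descending line and b the unit concave mid-course bump, with θ
running over 160° from module 1 to module 9.  Module 1 is therefore
monotone descending (it supplies the seed), module 9 monotone ascending,
and the correlation between modules is cos(Δθ): ≈ 0.94 for neighbours,
≈ 0.77 two apart.  This is the minimal structure that yields a single
connected chain of 9 BFS levels at PCC ≥ 0.91 over only five stage
points.  A family of Gaussian bumps — the more obvious choice — provably
cannot do this at T = 5: after mean-centering, neighbouring-bump
correlations collapse to ≈ 0.45–0.8 mid-course, and no width rescues the
chain.  The arc preserves the intended interpretation (an ordered
activation cascade) while making the correlation structure exact by
construction.

**Noise model.**  Counts are negative-binomial with mean
baseline · 2^signal · library factor and dispersion φ = 0.1
(var = μ + φμ²); library factors are log-normal (log2 sd 0.25); the
non-reference batch receives gene-wise multiplicative offsets (log2 sd
0.5).  Module amplitude is 8 log2 units — large, but in the range of
immediate-early TFs across a week of differentiation, and required for
within-module stage-profile correlations to exceed 0.99 given the
replicate-averaged noise (≈ 0.27 log2 units per stage mean).  The
baseline (2^10 mean counts, log2 sd 1) keeps planted genes expressed
through their off phase, because the emulated population is the
post-zero-filter expressed gene set.  Setting φ = 0 switches to Poisson
counts for noise-free-limit tests.

**Planted annotations.**  Module TFs are the TF list; each module carries
40 within-module TF→target regulatory edges labelled with one or two of
two source vocabularies; emitted gene sets are one target set per module,
a "late_pathway" set (targets of the last two modules), and the planted
descending/ascending gene lists.

**Recovery scoring.**  Recall is measured over the planted linear
monotone genes (within the expressed universe); precision counts a
selection as correct when the gene's noise-free signal is weakly monotone
in the claimed direction — edge-module genes (modules 1–2 and 8–9) are
genuinely monotone by construction and are not false positives.  Module
order recovery is Spearman between planted module index and assigned
level over reachable module TFs; regulatory recovery is the fraction of
planted TF→key edges found, plus the count of emitted edges absent from
the planted table (always 0 by the superset constraint).

**What the generator does not emulate.**  Gene–gene correlation beyond
the planted modules, gene-specific dispersions, length/GC biases,
outlier samples, and unevenly spaced or missing stages.  Passing tests
demonstrate correctness of the algorithms and sensible behaviour under a
realistic noise model, not performance on any particular real dataset.

## Numerical choices and degenerate inputs

- Thresholds in the DE statistic live strictly between distinct sorted
  values, so no sample ever sits on a threshold and tie conventions
  cannot bite; constant genes take the maximal per-split error
  min(|early|, |late|) and get p = 1.
- Permutation streams derive from a single seed via child generators (one
  per direction), keeping directions independent but jointly reproducible.
- PCC values are clipped to [−1, 1] after the normalized inner product;
  constant profiles yield NaN and are excluded from edges, level
  attachment and gating rather than erroring.
- BH q-values are the step-up minima capped at 1, checked against an
  independent implementation.
- In batch adjustment, genes with zero residual spread in any batch are
  shifted but not rescaled.
- Problem sizes in the test-suite simulations (2,000-gene null
  calibration, 500-gene DE oracle sweep, 100 random graphs ≤ 30 nodes,
  exhaustive hypergeometric check to N = 30) are chosen so each check
  runs in seconds while leaving the estimates' Monte-Carlo error an order
  of magnitude below the asserted margins.

## Known limitations

- The batch adjustment is location/scale only; strong gene-specific
  batch × stage interactions are out of model.
- The data-driven alternative to the fixed PCC cutoff is intentionally
  not a claim about how 0.91 maps to a p-value at T = 5; with five points
  the null distribution of PCC is too coarse for a sharp threshold.
- The permutation null ignores replicate/batch structure (labels are
  exchanged freely across all samples); a restricted within-batch
  permutation would be more faithful when batch effects survive
  adjustment.
- A non-TF gene's level membership is existential (one co-expressed TF
  suffices); no attempt is made to resolve multi-level genes to a single
  best level.
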