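# Methods

`omicbv` predicts family breeding values (BVs) for a quantitative trait
from two kinds of family-level molecular features — log2 family-mean
transcript abundances and SNP alternate-allele dosages called from the
same RNA-seq data — using two predictors, a feature-selection cascade,
and a cross-batch evaluation protocol. A synthetic-data generator with
hidden ground truth drives all end-to-end validation.

## Data model

The experimental unit is the open- or control-pollinated **family**: a
pool of seedlings sharing a seed parent. Families are grown and
sequenced in **batches** (different years, facilities, platforms);
78 families in batches of 45/11/22, five of the batch-one families
repeated in batch two. Each family contributes 1–3 pooled biological
replicates per batch. Replicate transcript counts are aggregated as
`log2(mean(raw counts) + 1)` — mean first, then the +1 offset, then the
log — and SNP genotypes are per-family diploid calls recoded to
alternate-allele dosage 0/1/2 (VCF input is filtered to biallelic SNVs
with QUAL > 30, MAF > 0.05 across families, and no missing genotypes).
Phenotypes are family breeding values estimated from progeny trials and
treated as known.

## Predictors

**Similarity-matrix kriging** (GBLUP-style best linear unbiased
prediction). With S the Pearson correlation matrix of families across
(feature-standardized) features, the training-block composite is
`Sigma = theta * S + (1 - theta) * I` (default theta = 1) and a test
family with similarity vector rho to the training families is predicted
as

    y_hat = mu + (theta * rho)' Sigma^{-1} (Y - mu),

the centered form of the similarity-weighted average `omega' Y` with
`omega = Sigma^{-1} rho`. Centering on the training mean makes the
predictor location-invariant; the literal uncentered weighted average is
available via `raw_weights=True` and coincides with the centered form
whenever the weights sum to one.

*Regularization.* A correlation similarity estimated from p features
carries O(1/sqrt(p)) sampling noise per entry. When p is comparable to
the number of training families, Sigma acquires small sample eigenvalues
that `Sigma^{-1}` amplifies catastrophically (we measured test-set r
collapsing from ~0.7 to ~0 near p ≈ n). `kriging_fit` therefore adds a
ridge `max(0.2, 2/sqrt(p))` to the diagonal by default. The ridge is
negligible at large p, curative at p ≈ n, and — because Pearson r is
scale-invariant — over-regularization only shrinks predictions toward
the mean without degrading correlation-based accuracy. `ridge=0.0`
recovers the plain solve; a 1e-6 diagonal jitter remains as the fallback
for numerically singular matrices (row-centering makes S rank-deficient
by one at theta = 1, so the jitter path is routinely exercised).

**Elastic net.** Coordinate-descent minimizer of

    (1/2n) * sum_i (y_i - b0 - x_i' b)^2 + lambda * (0.5*(1-alpha)*||b||_2^2 + alpha*||b||_1)

with internally standardized features, an unpenalized intercept, and
coefficients reported on the original scale. Convergence follows the
convention of the solver family this objective scaling comes from: a
sweep terminates the fit when the largest squared coefficient change
falls below `tol * var(y)` (tol = 1e-7), with active-set cycling between
full sweeps. An absolute coefficient-change criterion at 1e-7 was
measured to cost ~5e4 sweeps per fit at small lambda with p >> n, making
the prescribed tuning grid infeasible; the relative criterion gives
solutions identical at practical precision in ~1–2 ms per fit.
Tuning is a bootstrap grid search: 25 resamples of the training
families, alpha in 0.1..0.9 (step 0.1) by lambda in {1, 0.1, 0.01,
0.001}, scored by out-of-bag RMSE; a resample with an empty out-of-bag
set is redrawn; ties prefer the smaller lambda, then the smaller alpha.

**Combination.** The combined prediction is the per-family arithmetic
mean of the SNP and transcript predictions from the same model.

## Feature-selection cascades

Transcripts: (ALL) keep transcripts with mean log2 family expression
>= 3 (inclusive); (setA) one-way batch ANOVA on family means — families
grown in more than one batch are excluded from the test because their
means pool batches — with two-groups local-FDR adjustment, removing
transcripts with lfdr < 0.05; (setB) greedy collinearity pruning: while
any pair has |r| > 0.5 (a feature explaining more than 25% of another's
variance), remove from the most-correlated pair the member with the
larger mean absolute correlation to all remaining features, ties
removing the later column; (setC) keep transcripts with training-set
|Spearman r| > 0.05 against BVs.

SNPs: (ALL) batch ANOVA at unadjusted p < 0.05; (setA) relative
variance — sample variance of dosages divided by mean dosage — strictly
greater than 1 (note that a Binomial(2, p) locus has expected ratio
1 − p < 1, so this screen selects loci whose among-family variation
exceeds binomial sampling, i.e. real frequency differences among
families); (setB) the same pruning; (setC) one-way ANOVA of training
BVs grouped by dosage class {0,1,2}, keeping unadjusted p < 0.05;
classes with no members are dropped and SNPs with fewer than two
occupied classes are untestable and removed. All phenotype-dependent
screens receive only the training phenotype table, which structurally
prevents test leakage.

The local FDR estimator follows the two-groups empirical-Bayes
construction: pi0 from the tail-proportion grid lambda = 0.05..0.95
(step 0.05) extrapolated to lambda -> 1 with a cubic least-squares fit
(clipped to (0, 1]); the marginal density of probit-transformed
p-values by Gaussian kernel; lfdr = min(1, pi0*f0/f) regularized to be
monotone non-increasing toward p -> 0. Benjamini–Hochberg is available
as a simpler alternative (`multiple_testing="BH"`).

## Evaluation

Cross-batch splits assign any family present in more than one batch to
training; the three canonical designs are train batch 1 → test 2+3
(45/33), train 1+3 → test 2 (67/11), and train 1+2 → test 3 (56/22).
Accuracy is the Pearson correlation of predicted vs observed BVs with
the two-sided p of the simple-regression t-test (n−2 df); degenerate
(constant) predictions are flagged and reported as r = 0, p = 1.
Whether combining data types adds information is tested with a nested
linear-model F-test (obs ~ single vs obs ~ single + combined, F(1, n−3));
a Hotelling–Williams dependent-correlation test is available via
configuration since the original comparison procedure is not fully
specified. The full grid is {kriging, elastic net} × {snps, transcripts,
combined} × {ALL, setA, setB, setC}; cell failures (e.g. a stage
filtered to nothing) are recorded and the grid continues.

## Synthetic-data generator

The generator emulates the statistical structure such a study rests on,
with hidden truth for recovery tests. Defaults were chosen once to
place the simulation in the qualitative regime the pipeline is designed
for — unfiltered cross-batch prediction is poor, the cascade recovers
accuracy, and combining data types helps — not to reproduce any
particular numeric value.

*Genetics.* Per SNP j, allele frequency p_j ~ U(0.15, 0.5) shared
within LD blocks of 5 (block members are near-copies, copy probability
0.995, so collinearity pruning is information-lossless); family dosages
g_ij ~ Binomial(2, f_ij). A set of latent family-structure axes
(4 by default, standard normal per family) represents provenance-like
gradients: 12% of blocks are "structured", drawn at lower MAF
(U(0.05, 0.2)) with the axis shifting their per-family sampling
frequency by a loading in (0.14, 0.2). The low MAF and the added
frequency variance are what make the relative-variance screen
informative. Only axis 0 tracks the breeding value: causal SNPs
(2% of loci) live in axis-0 blocks and

    BV_i = sum_{j causal} a_j (g_ij − 2 p_j) + e_i,   e_i ~ N(0, 0.25),

with a_j ~ N(0, scale^2/n_causal) and half of the causal effects signed
with the axis-0 loading (directional selection aligns allele
frequencies with effect signs in a breeding population). Batch-biased
dosage calls: 5% of SNPs are re-sampled in one batch with the frequency
shifted by ±0.35 — strong enough that the batch ANOVA removes nearly
all of them, as intended.

*Expression.* Transcript baselines are N(5, 2.2) on the log2 scale.
A 10% minority of transcripts is heritable: their log2 family mean adds
`b_t * z~_i`, where z~ is the standardized BV plus N(0, 1) family
"expression state" noise — juvenile expression tracks genetic merit only
imperfectly, which caps the transcript channel near r ≈ 0.7 no matter
how many transcripts a model uses — and b_t has magnitude
0.18 * U(0.7, 1.3) with random sign. Signal transcripts are
co-regulated in modules of 5 (shared factor, loading 0.45), and 35% of
null transcripts form co-expression modules with loading 1.0, so the
pruning stage has genuinely redundant structure to remove on both
sides. Batch effects hit 60% of transcripts with a bimodal shift
(magnitude 2.0*(0.75+|N(0,0.5)|), random sign, batches 2 and 3 relative
to batch 1) plus family-level technical noise (sd 1.0) in the
non-reference batches; the shifts are always large enough for the lfdr
filter to detect, mirroring a study in which the overwhelming majority
of transcripts shows batch association, while the family-level noise is
what actually cripples unfiltered cross-batch prediction. Replicate
counts are negative binomial with mean `size_factor * 2^(log2 mean)`
(size factors U(0.5, 1.5)) and size parameter 10 (larger = closer to
Poisson); replicates per family-batch are 1/2/3 with probabilities
0.15/0.25/0.60.

*What the generator does not model:* read-level artifacts (GC, length,
mapping bias), isoform structure, genuine pedigree relatedness (an
exchangeable-family assumption mirrors the near-zero relationships in
the motivating data), dominance/epistasis, and correlation between
batch effects and biology. Passing recovery tests therefore shows the
pipeline behaves correctly *given* this generative structure, not that
real data satisfies it.

## Problem sizes and numerical choices

Library defaults generate 10,000 transcripts and 10,000 SNPs (the
generator supports the 1e4–1e5 range). The test suite and the
acceptance script run `SyntheticConfig.scaled(2000, 6000)` — reduced
feature counts with the default signal *fractions* preserved — which
keeps a full 20-study recovery experiment to a few minutes while
leaving every cascade stage populated; the type-I checks use smaller
matrices still (400–800 features), and the permuted-phenotype
calibration runs the grid with a single elastic-net grid point and two
bootstraps, since the calibration of the accuracy p-value does not
depend on the tuning search. Other numerical conventions: sample
variance uses the n−1 denominator; threshold comparisons are inclusive
(>= / >) exactly as stated per filter; Spearman of a constant vector is
reported as 0 with a degenerate flag so all-pairs reports never abort;
monomorphic SNPs are excluded from the GRM (p = 0 or 1 carries no
relationship information) and zero-mean-dosage SNPs are dropped before
the relative-variance screen.

## Known limitations

- The elastic-net tuning surface is nearly flat when signals are weak
  and n is small; the selected (alpha, lambda) varies across seeds, as
  it would have in the original bootstrap procedure. Accuracy summaries
  should be averaged over seeds.
- Kriging with theta = 1 relies entirely on the estimated similarity;
  the default ridge stabilizes it, but similarity matrices built from a
  handful of phenotype-screened features are still selection-biased
  toward the training phenotype (visible as a small setC dip for
  transcript-only kriging).
- The cascade's setC SNP set can be very small at reduced problem
  sizes; cells with fewer than two usable features are reported as
  degenerate rather than extrapolated.
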