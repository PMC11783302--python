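# Methods

This note records the models, the simulation, the numerical choices, and
the limits of what the test suite demonstrates.

## Data model and preprocessing

A dataset is an `N × G` matrix of nonnegative read counts, per-sample class
labels in `1..C`, unique gene names and sample ids. Preprocessing runs in a
fixed order:

1. **Gene filters.** Remove genes with any NaN; genes whose maximum count is
   0; and low-expressed genes with fewer than 5 counts in more than 75% of
   the samples of *every* class. The quantifier matters: requiring the
   low-count condition in every class keeps genes expressed in a single
   class, which are plausible markers. The alternative reading (low in *at
   least one* class) is available via `low_count_quantifier="any"`. Filtering
   is idempotent.
2. **Normalization.** Counts-per-million per sample, then `log2(1 + cpm)`.
   The pseudocount of 1 is required because CPM values of 0 occur; it is
   configurable. A sample with zero total count is an error (such samples
   must be excluded upstream).
3. **Split.** Stratified 60/40 train/test by default. Plain random splitting
   can empty a small class in imbalanced data; stratification is the
   standard choice when evaluation uses balanced accuracy. Per-class train
   counts are round-half-up of `fraction × class size`, adjusted by ±1 on
   the largest classes to hit the global target, with at least one sample
   per class on each side.
4. **Standardization.** Column z-scores using means and standard deviations
   computed from the training samples only (population convention).
   Standard deviations below 1e−12 are replaced by 1 with a warning so the
   transform stays invertible. No test-set statistic enters the scaler.

## Classifiers

All families consume the standardized matrix and predict class
probabilities over `1..C`.

- **Logistic regression (L1/L2)** is fit with scikit-learn's SAGA solver
  (cross-entropy plus penalty, 1000-iteration cap; non-convergence is a
  warning, not an error, since near-boundary solutions are still usable).
  Probability gradients with respect to the input are closed-form:
  `∂p_c/∂x = p_c (W_c − Σ_k p_k W_k)` for softmax, `p(1−p)W` for the
  binary sigmoid.
- **MLP**: one or two dense hidden layers, each followed by batch
  normalization and ReLU, then a linear softmax head (a 2-logit softmax is
  the binary sigmoid reparameterized). Trained by minibatch SGD, momentum
  0.9, weight decay 1e−4, 25 epochs, learning rate 0.1 stepping to 0.01 at
  epoch 13 and 0.001 at epoch 23, batch size 32. Forward and backward
  passes are explicit numpy; at inference batch norm is an affine map using
  running statistics, so input gradients are exact. Singleton minibatches
  are skipped (batch statistics undefined).
- **GNN**: genes are nodes of a co-expression graph built from pairwise
  Pearson correlations on training samples, keeping the `edge_budget`
  edges of largest |r| with weight |r| (the symmetric-normalized
  propagation `D̃^{−1/2}(A+I)D̃^{−1/2} x W` assumes nonnegative weights, so
  the absolute value is taken; constant genes correlate to 0). After each
  of one or two convolution layers, features are max-pooled over the pairs
  produced by one level of greedy heavy-edge matching (repeatedly merge the
  unmatched pair with the heaviest edge; merged edge weights are summed;
  leftovers stay singletons). A dense softmax head reads the flattened node
  features. Trained with Adam, weight decay 1e−4, 15 epochs, learning rate
  0.01 stepping to 0.001 at epoch 8 and 1e−4 at epoch 14.

  The default edge budget is `G/4`. Dense budgets admit many spurious
  noise–noise correlation edges whose smoothing mixes informative genes
  with noise and measurably hurts held-out accuracy; a sparse graph keeps
  the strongest co-expression structure (e.g. redundant blocks) and leaves
  weakly correlated genes near-isolated. The budget is exposed everywhere
  a graph is built, and graphs are rebuilt from scratch when retraining on
  gene subsets, since subsetting perturbs the graph structure.
- **Gradient-boosted trees** use XGBoost (learning rate 1.0, depth 3, 50
  rounds, single thread) and expose per-gene total split gain. Training is
  deterministic for fixed hyperparameters, so this family contributes a
  single ranking rather than replicates.

Model quality is reported as balanced accuracy (mean per-class recall),
which is insensitive to class imbalance.

## Gene rankings

Higher score = more important everywhere; rank ties are broken
lexicographically by gene name (deterministic and recorded in the ranking
file header). Filter statistics are computed on training samples.

- Variance uses the population (1/N) convention; the ordering is identical
  under 1/(N−1).
- PCA uses the |loading| on the unit leading eigenvector of the gene–gene
  covariance (computed by SVD of the centred matrix; no G × G covariance is
  materialized). Sign indeterminacy is harmless under the absolute value; a
  near-degenerate leading eigenvalue triggers a warning because loadings
  within the eigenspace are then arbitrary.
- Mutual information uses the kNN estimator (k = 3 by default) for a
  continuous feature against the discrete class; negative estimates are
  clipped to 0.
- Differential expression is a Welch unequal-variance t-test per gene on
  the log-CPM values, scored as −log10(BH-adjusted p). With C > 2 classes
  every unordered pair is tested, the minimal raw p per gene is kept (and
  the winning pair recorded), then BH is applied across genes. Adjusting
  before or after the min-over-pairs reduction is a genuine choice;
  min-then-adjust is used because the ranking is defined on the per-gene
  summary. Running the t-test on log-CPM rather than raw counts matches
  the approximate-normality assumption of the test. Dedicated
  negative-binomial GLM testers (DESeq2, edgeR) are deliberately not
  reimplemented; their output enters through the ranking TSV import path
  with scores on the same −log10(adjusted p) scale.
- Embedded scores: |W_g| (binary) or mean over classes of |W_cg|
  (multi-class) for logistic models; total gain for boosted trees, with
  unused genes at exactly 0 (the count of nonzero-gain genes is part of
  the ranking and is used to mask overlap cells and truncate ORA lists).

## Integrated gradients and prediction gaps

IG uses a midpoint Riemann sum with 128 steps by default; the completeness
residual `|Σφ − (f_c(x) − f_c(x′))|` is reported per sample and is the
convergence diagnostic (it decreases as steps double until the float
accumulation floor, around 1e−7 for ~10³ genes). Baselines follow the task:
mean of normal-class training samples for binary problems (scores computed
on the tumour class), mean of all training samples for multi-class (scores
computed per class and averaged). Per-class aggregation averages
L2-normalized absolute local vectors over correctly classified training
samples; all-zero attribution vectors are excluded with a warning rather
than propagating NaN.

Prediction-gap curves evaluate the model at every mask count m = 0..G by
default; a stride option evaluates a subgrid for large G, and the scalar is
then computed on that subgrid and labelled approximate. The random masking
order uses a seeded permutation. PG requires `f_c(x) > 0`; experiment-0
aggregation restricts to correctly classified training samples (optionally
a seeded subsample to bound runtime) and reports per-replicate means with
cross-replicate mean ± std, plus 100 − PGI (the percentage of top-ranked
genes maskable before the model is disturbed).

## Experiments, overlaps, ORA

Retraining experiments refit a model family from scratch on the g highest-
(experiment 1), lowest- (experiment 2), or randomly-ranked genes over a
grid, default {1, 5, 10, 50, 100, 500, 1000} ∩ [1, G]; the full unit-step
grid is prohibitively slow and adds little. Each ranking replicate is
paired with one retraining seed (a cartesian product would square the
cost). Overlap matrices report mean top-10 (lower triangle) and top-100
(upper triangle and within-method diagonal) overlap percentages over all
replicate pairs; single-ranking methods have a diagonal of 100 by design,
and methods with fewer nonzero scores than k are masked.

ORA uses the exact hypergeometric upper tail (enrichment only) with the
universe set to the post-filter gene list of the analysed dataset — a
choice that differs from web annotators with fixed backgrounds, so results
against external collections are comparable only qualitatively. BH is
applied across the sets of a collection; methods with fewer than `top_n`
nonzero-score genes are tested with all their nonzero genes. Each method's
top-10 significant sets are cross-flagged when they appear in another
method's top-100 significant sets; ML-based methods contribute their first
replicate.

## Synthetic data

Counts are negative-binomial with variance μ + φμ² (gamma–Poisson mixture,
dispersion φ = 0.1 by default), the standard overdispersed model for bulk
RNA-seq. Per-gene baseline log2 means are uniform on (0, 8) so the
low-count filter is exercised at the bottom of the range. Differential
expression multiplies the mean by `2^lfc` for a disjoint set of genes per
class (default 20 genes per class at lfc = 2, a moderate planted effect).
Class imbalance is supported directly through per-class sample counts.

Redundant blocks share a per-sample standard normal factor z on the
log-mean scale: μ_gn = m_g · exp(λz_n − λ²/2). For large means the pairwise
count correlation is `(e^{λ²} − 1) / ((1+φ)e^{λ²} − 1)`, and λ is solved
from the requested correlation (feasible when ρ(1+φ) < 1; infeasible
configurations are rejected). Blocks are assigned classes round-robin and
can carry their own fold change, which is how the "low-ranked genes are
still informative" condition is constructed: when signal-bearing blocks
cover most genes, the bottom of any ranking still separates the classes.

What the generator does *not* emulate: batch effects, library-size
confounding with class, tissue-specific covariance beyond block structure,
or realistic gene-set topology (the toy GMT builder plants one set per
class plus random decoys). Passing tests therefore demonstrate internal
correctness and qualitative reproduction of the masking/retraining/overlap
phenomenology under controlled conditions — not that any particular public
dataset would yield the same numbers.

## Problem sizes and determinism

Default study conditions are desk-scale: the demo configuration uses 2
classes × 100 samples, 10³ genes, 2 ranking replicates, IG with 64 steps
capped at 10 samples per class, and a retraining grid up to 100 genes; the
recovery and null studies use 2 × 10³ genes and 100 samples per class.
These sizes were chosen so a full run takes well under a minute on one CPU
while keeping every estimate away from small-sample degeneracy. All
randomness flows from explicit seeds (generation, splitting, training
initialization and batch order, subsampling, random masking), so reruns of
a configuration are bit-identical; the only non-deterministic output is
wall-clock timing in the run manifest.

## Known limitations

- The MLP/GNN training loops are plain numpy and single-threaded; they are
  sized for 10³–10⁴ genes and hundreds of samples, not for GPU-scale work.
- The kNN MI estimator is biased near zero and clipped; extremely small
  classes (< k+1 samples) are rejected rather than estimated.
- The Welch-t ranker is a normal-theory approximation on log-CPM, not a
  count-model test; import DESeq2/edgeR results where exact NB inference
  matters.
- Heavy-edge matching is a greedy 2-approximation of maximum-weight
  matching; coarsening results depend on edge-weight ties only through the
  deterministic stable sort.
- ORA assumes the supplied universe; q-values are comparable across methods
  within a run, not across tools with different backgrounds.
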