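# Methods

This note documents the models implemented in `bcsubtype`, the assumptions
behind the synthetic-data generator, the numerical choices that affect
results, and the limitations a user should keep in mind.

## Nearest-centroid subtyping

A sample's log2 expression vector is centered by subtracting a per-gene
reference profile (both on the log2 scale, so the subtraction realizes a
Log2ratio against the reference), restricted to the genes shared by the
matrix, the reference and the centroid table, and correlated with each class
centroid. The call is the class with the highest correlation.

* **Metric.** Spearman rank correlation with average (fractional) ranks for
  ties is the default; Pearson is available for shrunken-centroid-style
  callers that also exclude the Normal-like class. A profile that is
  constant after centering has no defined rank correlation and yields an
  `UNCLASSIFIABLE` call with the reason recorded, never a silent guess.
* **Tie-break.** Exactly equal correlations are resolved by alphabetical
  class order. Ties are measure-zero on real data but the rule makes every
  pipeline output reproducible.
* **Gene overlap.** Classification requires a configurable minimum fraction
  (default 80%) of centroid genes to survive the intersection; real
  platforms occasionally lack a panel gene, so partial overlap is tolerated
  but bounded, and the missing genes are named in the error otherwise.
* **Single-sample contract.** Centering, ranking and correlation are
  computed per sample (per-column operations and per-sample vector
  products), so a sample's call and correlation vector are bit-identical
  whether it is classified alone or inside any batch. The test suite
  enforces exact equality, not approximate agreement.

## Reference profiles

Two construction strategies are provided.

**ER-stratified median.** The per-gene median over a random subset with a
fixed ER+/ER− proportion (default 60/40, the convention of the original
assay training). The ER+ quota is round-half-up of `size * fraction`;
samples with unknown ER status are ineligible. This is the classical
approach and is deliberately retained as the comparison baseline: its output
depends on the sampled subset.

**AWCA (average of within-class averages).** Given any preliminary
classification (a median-reference run, or published calls), the per-gene
mean is computed within each called class over the whole cohort, and those
class means are averaged with equal weight. Classes explicitly excluded, or
with fewer than `min_class_size` (default 10) called samples, are dropped
from the outer average — small classes contribute unstable means, and the
default mirrors the practical situation where the Normal-like class is too
small to average safely. At least two classes must remain. The pipeline
performs exactly one re-classification round against the AWCA reference; it
is not iterated to convergence.

**Exact arithmetic for the class means.** The defining property of the
double average is independence from class sizes: replicating every sample of
a class must not move the reference. Floating-point summation cannot
guarantee that bit-for-bit for arbitrary replication factors, so the
within-class and outer means are accumulated in exact rational arithmetic
(float64 values are dyadic rationals; sums use a common power-of-two
denominator) with a single final rounding to float64. The invariance then
holds exactly for any replication factor, and the cost is a fraction of a
second per reference at the default cohort scale.

**Recommended use.** A warning (not an error) is emitted when the reference
subset has fewer than 50 samples; robust references want at least 50–100.

**Stability experiment.** For each subset size and replicate, a fresh
ER-stratified subset seeds a median reference; the whole cohort is
classified against it (strategy `median`), and those calls seed one AWCA
round (strategy `awca`). The report records concordance with the true
labels and all within-strategy pairwise concordances; replicates whose
subset is infeasible for the ER strata are skipped, logged and counted.
All randomness flows from one seed through `numpy.random.SeedSequence`.

## Risk of recurrence

The score is `sum_k w_k * rho_k + w_T * T` over the per-class correlations
plus a tumour-size term, optionally rescaled affinely (`a*raw + b`, e.g. to
a 0–100 range), and binned into low/intermediate/high with boundary values
assigned to the lower group. Coefficients and thresholds are
configuration-supplied and never hard-coded: the published Cox-model
coefficients belong to the original assay and must be transcribed by the
user; the shipped `configs/ror_placeholder.yaml` contains clearly labelled
synthetic round values that only exercise the code path. The Normal-like
class is excluded from the placeholder weighting, as it is not used in ROR
models. Batch scoring collects per-sample failures (missing tumour size,
missing correlations) instead of dropping them.

## Feature selection

* **Fisher score**: `sum_k n_k (mu_k − mu)^2 / sum_k n_k sigma_k^2` with
  population variances and the denominator floored at 1e-12, so a gene with
  distinct means but zero within-class variance gets a large finite score.
* **Mutual information / chi-squared**: each gene is discretized into
  per-gene quantile bins (default 4; duplicate quantile edges collapse, and
  a single occupied bin scores 0), then the plug-in MI in bits, or the
  Pearson chi-square statistic, of the bin-by-class contingency table.
* **Rank-correlation filter**: the class label enters as a one-vs-rest
  indicator; the score is the maximum over classes of |Spearman rho| between
  expression and the indicator. This symmetric encoding was chosen because
  a five-level label has no natural ordering.
* **Pairwise DEG contrasts**: for every unordered class pair, a per-gene
  two-sample t-statistic on log2 values, by default with empirical-Bayes
  variance moderation: per-gene pooled variances are shrunk toward a
  scaled-inverse-chi-square prior whose parameters (d0, s0^2) are fitted by
  matching moments of the log variances (with a Newton inverse-trigamma
  solve); the moderated t has d0 + d degrees of freedom. The implementation
  is cross-checked in the test suite against the Bioconductor reference
  implementation on a fixture and agrees to ~1e-8 relative error.
  p-values are Benjamini–Hochberg adjusted within each contrast; the
  significant list (adjusted p < 0.05 by default) is sorted by ascending
  adjusted p with deterministic tie-breaks.
* **Union signature (limmaN)**: the union over contrasts of the top N
  significant genes each (or all, if fewer). Taking the union of
  significance-truncated lists makes the signature monotone in N.
* **Backward elimination**: each run shuffles the gene order (seeded),
  sweeps the genes repeatedly and removes a gene whenever the trainer's
  cross-validated accuracy without it exceeds the current accuracy by more
  than `gain_threshold` (default 0.001 absolute), until a pass removes
  nothing; the final signature is the union of every run's kept set. The
  default trainer is the elastic-net softmax model under 5-fold seeded
  stratified cross-validation (an inner-loop speed choice; the fold count is
  configurable). Per-run kept sets and failed runs are recorded in the
  signature provenance.

## Elastic-net multinomial logistic regression

The objective is `(1/n) * multinomial NLL + l1 * sum|W| + (l2/2) * sum W^2`
with unpenalized intercepts, on per-gene z-scored features (standard
deviations floored at 1e-8; the training statistics are stored in the model
and re-applied at prediction). Optimization is proximal gradient descent
(ISTA) with backtracking line search on the smooth part and
soft-thresholding for the L1 term — chosen because it produces exact zero
weights, which the sparsity accounting (non-zero means |w| > 1e-8) relies
on. The penalized objective decreases monotonically; iteration stops at a
relative objective change below 1e-6 or at 1,000 iterations with a warning.
Zero initialization makes the fit deterministic without consuming
randomness. Hyperparameters are selected by seeded stratified k-fold
cross-validation (10 folds by default, reduced with a warning when the
smallest class is smaller) over a grid (default {0.01, 0.1, 1.0}^2), ties
resolved toward the smaller l1 then l2, followed by a refit on all data.
Because regularized-regression objectives are scaled differently across
software, hyperparameter values do not transfer between implementations;
the l1 = 0 path is cross-checked against scikit-learn's ridge-penalized
solver under the appropriate reparameterization in the test suite.

Predictions are softmax membership probabilities computed per sample, with
the arg-max call under the same alphabetical tie-break as the
nearest-centroid path.

## Evaluation

Concordance is the percentage of matching calls over samples matched by id
(never by position); `UNCLASSIFIABLE` calls are excluded pairwise and the
exclusion count reported. Cohen's kappa uses marginal-product expected
agreement; the degenerate case of two identical constant call sets is
defined as 1. Macro-averaged recall and precision are unweighted means over
classes with a nonzero denominator, with excluded classes reported.
Pairwise concordance distributions over m call sets enumerate all C(m, 2)
pairs and report the sample standard deviation (0 by convention for a
single pair).

## Synthetic cohorts

The generator draws `x[g, s] = baseline[g] + dev[g, class(s)] + N(0,
noise_sd)`, with the planted centroid table holding the deviations `dev` on
the Log2ratio scale. The default configuration — the package's reference
study condition, not a tuning knob — is: 1,000 genes; 100 class-informative
genes assigned round-robin with a +2.0 log2 shift in their class (a
four-fold change, typical of subtype marker genes); five classes sized
(120, 100, 60, 50, 20) echoing the luminal-heavy composition and small
Normal-like class of real breast-cancer cohorts; ER+ probabilities (0.95,
0.9, 0.1, 0.4, 0.7) per class, reproducing the luminal–ER association that
makes ER-stratified subsets class-imbalanced; noise SD 1.0 on the log2
scale; 10% ambiguous samples drawn from an equal mixture of their class
centroid and a random partner centroid, with the pair recorded; lognormal
tumour sizes (log-mean 0.7, log-sd 0.45, i.e. a ~2 cm median). Planted
differentially expressed blocks shift the two named classes by ±shift/2,
so the full shift separates exactly that pair while disjoint pairs remain
null for those genes.

What the generator does **not** emulate: count noise and mean–variance
dependence (negative binomial), library-size and normalization artifacts,
RSEM/FPKM processing differences, correlated gene modules, or batch
effects. Passing tests therefore demonstrate the correctness and the
relative robustness of the procedures under the stated noise model, not
absolute performance on any real cohort; in particular, references built
under one normalization scheme should not be applied to data processed
under another.

In the noiseless, unambiguous limit the cohort is a fixed point of the whole
stack: the cohort median recovers the baseline exactly (every class is a
minority), centering leaves the pure class deviations, and median, AWCA and
classification chains are all exactly reproducible at 100% concordance.

The sparse-softmax generator used for recovery studies draws standard-normal
features, places coefficients of magnitude 2.5 with alternating sign on 8 of
40 genes across 3 classes, and samples labels from the implied
probabilities; 500 samples give a comfortably identified support at
l1 = 0.05.

## Problem sizes and determinism

The shipped experiments run at desk scale: a 350-sample cohort, 10
replicates per subset size for the stability experiment, 10-fold
cross-validation on signatures of tens to hundreds of genes. These sizes
were chosen so the full study re-runs in minutes on one CPU while leaving
the qualitative contrasts (median vs AWCA dispersion, signature recovery,
sparsity behaviour) clearly resolved. Every stochastic path — subset
sampling, cohort simulation, fold assignment, gene-order shuffling — is
reachable only through explicit integer seeds, spawned from a single root
via `SeedSequence`; two runs with the same seed are bit-identical, including
the CLI's output files (provenance headers carry the tool version, a config
hash and the seed, and no timestamps).

## Known limitations

* The AWCA pipeline performs one re-classification round by design; the
  fixed point of further iteration is not characterized.
* ROR scoring is only as meaningful as the user-supplied coefficients; the
  placeholder configuration is for smoke testing, and no survival modelling
  is included to validate a choice of weights.
* The filter statistics use simple plug-in estimators (quantile binning,
  empirical MI) without bias correction; rankings are comparable within a
  dataset, not across datasets.
* Backward elimination is a greedy heuristic; with correlated features the
  kept set varies across shuffled runs, which is precisely why the union
  across runs is taken.
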