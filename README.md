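# bcsubtype

Robust PAM50-style intrinsic subtyping of breast-cancer RNA-seq profiles.

Breast tumours fall into five transcriptional "intrinsic subtypes" (Luminal A,
Luminal B, Her2-Enriched, Basal-like, Normal-like) with distinct prognosis and
treatment implications. The standard PAM50 caller assigns a subtype by
correlating a sample's 50-gene **Log2ratio** profile with five class
centroids. The Log2ratio step — subtracting a per-gene *reference profile*
built from a cohort subset with a fixed ER+/ER− proportion (typically 60/40) —
makes the call depend on which samples happened to be chosen for the
reference. This package implements that classical pipeline, a robust
alternative for reference construction, and a reference-free machine-learning
caller, together with the evaluation harness to compare them. It is aimed at
computational biologists who need reproducible, single-sample subtype calls
from RNA-seq expression matrices.

## What's inside

**Nearest-centroid classification** (`bcsubtype.pam50`). For sample *s* with
log2 expression *x* and reference *r*, the centered profile is
*x − r*; the call is `argmax_k rho(x − r, c_k)` over class centroids *c_k*
with Spearman rank correlation `rho` (a Pearson variant with class exclusion
supports shrunken-centroid-style callers). The contract is strictly
single-sample: calls never depend on the rest of the batch.

**Reference construction** (`bcsubtype.reference`). Two strategies:

* *ER-stratified median*: per-gene median over a random subset with a fixed
  ER+/ER− ratio — the classical approach, sensitive to subset choice;
* *AWCA* ("average of within-class averages"): starting from a preliminary
  classification, `ref[g] = (1/K) * sum_k mean_{s in class k} x[g, s]` —
  double averaging equalizes class contributions, so the reference is
  exactly invariant to how many samples each subtype has.

`stability_experiment` replicates both strategies over random subsets of
decreasing size and reports concordance-to-truth and pairwise concordance
distributions.

**Risk of recurrence** (`bcsubtype.ror`): `ROR = sum_k w_k * rho_k + w_T * T`
with configurable weights, tumour-size term and low/intermediate/high
thresholds (coefficients are user-supplied; see `configs/ror_placeholder.yaml`).

**Feature selection** (`bcsubtype.features`): Fisher / mutual-information /
chi-squared / rank-correlation filters; per-contrast moderated t-tests
(empirical-Bayes variance shrinkage, BH adjustment) with the "union of the
top N genes per pairwise contrast" signature; randomized-order backward
elimination driven by cross-validated accuracy.

**Elastic-net softmax caller** (`bcsubtype.mlr`): multiclass logistic
regression minimizing `(1/n)*NLL + l1*sum|W| + (l2/2)*sum W^2` by proximal
gradient descent (exact zeros for the L1 term), with stratified k-fold
cross-validation and (l1, l2) grid search; predictions are per-class
membership probabilities.

**Evaluation** (`bcsubtype.metrics`): concordance, Cohen's kappa, confusion
matrices, macro-averaged recall/precision, pairwise-concordance
distributions — always matched by sample id.

**Synthetic cohorts** (`bcsubtype.simulate`): seeded generator with planted
class centroids, per-gene Gaussian noise on the log2 scale, class-dependent
ER status, ambiguous two-centroid mixture samples, planted pairwise-DE gene
blocks, and the balanced training-split constructor.

## Worked example

```python
import bcsubtype as bc

cohort = bc.simulate_cohort(bc.SimulationConfig(seed=0))   # 1000 genes x 350 samples
result = bc.awca_pipeline(cohort.expression, list(cohort.annotations),
                          cohort.planted_centroids, bc.SubsetSpec(size=200, seed=1))
print(f"median-reference PAM50 vs truth: "
      f"{bc.concordance(result.preliminary_calls, cohort.true_labels):.2f}%")
print(f"AWCA-reference PAM50 vs truth:   "
      f"{bc.concordance(result.calls, cohort.true_labels):.2f}%")

report = bc.stability_experiment(cohort.expression, list(cohort.annotations),
                                 cohort.planted_centroids, sizes=[200, 100, 50],
                                 replicates=10, truth_labels=cohort.true_labels, seed=0)
print(report.summary_frame()[["strategy", "subset_size",
                              "pairwise_concordance_mean",
                              "pairwise_concordance_sd"]].round(2).to_string(index=False))
```

prints

```
median-reference PAM50 vs truth: 94.86%
AWCA-reference PAM50 vs truth:   97.14%
strategy  subset_size  pairwise_concordance_mean  pairwise_concordance_sd
    awca           50                      99.89                     0.15
    awca          100                      99.94                     0.12
    awca          200                     100.00                     0.00
  median           50                      97.75                     0.99
  median          100                      98.29                     0.88
  median          200                      98.89                     0.56
```

One AWCA round on top of a median-reference classification both
improves agreement with the planted labels and, across ten random reference
subsets per size, makes the resulting classifications far more concordant
with each other — the dispersion of median-based calls roughly doubles as
the subset halves, while AWCA stays within a fraction of a percent.

The same pipeline is available from the shell:

```sh
bcsubtype simulate --out-dir cohort --seed 0
bcsubtype build-reference --method awca --expression cohort/expression.tsv \
    --annotations cohort/annotations.tsv --centroids cohort/centroids.tsv \
    --out awca_ref.tsv --subset-size 200 --seed 1
bcsubtype classify --expression cohort/expression.tsv --reference awca_ref.tsv \
    --centroids cohort/centroids.tsv --out calls.tsv
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data assumptions,
numerical choices and known limitations.
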