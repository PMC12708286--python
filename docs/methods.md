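# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `mitodx`. Nothing here
states an empirical result that the test-suite or `scripts/acceptance.py`
does not itself compute.

## The discovery chain

The package targets the common multi-cohort microarray design: several
independently collected case/control cohorts (Control = non-tumor,
Treat = tumor), each a genes × samples matrix on a log2 scale after
platform-level processing. Training cohorts are merged on their shared
genes and batch-corrected; validation cohorts are normalized per cohort
and never enter any fitting step.

### Preprocessing

* **Probe collapse** — probes flagged unmapped or ambiguous are removed;
  a gene's remaining probes are averaged per sample. The arithmetic mean
  is the default and the median is available as an option
  (`collapse_probes(..., stat="median")`): both conventions circulate in
  the microarray literature and the difference is immaterial for
  well-behaved probes, so the package exposes the choice rather than
  hiding it.
* **KNN imputation** — gene-wise: for a missing entry, the k = 10 genes
  observed at that sample that are nearest in Euclidean distance over
  mutually observed samples donate their values with 1/distance weights;
  a zero-distance neighbour is copied exactly. k = 10 and inverse-distance
  weighting follow the defaults of the classical expression-imputation
  literature. Observed entries are never altered. The implementation is
  exact rather than approximate (no distance rescaling for partial
  overlap), which is affordable at the matrix sizes this package targets.
* **Automatic log2 rule** — pooled over all entries: transform with
  log2(x+1) when q99 > 100, or when (max−min) > 50 and q25 > 0. Pooled
  (rather than per-sample) quantiles make the decision a property of the
  cohort, not of its noisiest array. The rule is idempotent on log-scale
  output.
* **Quantile normalization** — every column's order statistics are
  replaced by the across-column mean of order statistics; ties within a
  column receive the mean of the reference values at their tied ranks, so
  tied inputs stay tied and the map is deterministic.
* **Batch correction** — the parametric empirical-Bayes location–scale
  model: per-gene standardization against an intercept + group design,
  per-batch gene-wise location γ̂ and scale δ̂² shrunk toward a normal /
  inverse-gamma prior whose hyperparameters are moment-matched across
  genes, with the conditional posterior means iterated to a relative
  tolerance of 1e-4 (cap 100 iterations). The Control/Treat indicator is
  always protected as a covariate; an unprotected run on a group-imbalanced
  merge would absorb real signal into the batch term. A single batch is
  returned unchanged with a warning. Because the shrunken locations need
  not cancel exactly across batches, per-gene grand means can move by a
  small amount (order 1e-2 on log2 data) even for balanced designs; this
  is inherent to empirical-Bayes shrinkage, not a defect.

### Differential expression

Gene-wise two-group linear fits (log2FC = Treat − Control mean difference,
pooled variance, df = n₁+n₂−2) followed by empirical-Bayes moderation.
The prior degrees of freedom d₀ and prior variance s₀² are estimated by
moment matching on log s²: with e = log s² − ψ(df/2) + log(df/2),
ψ′(d₀/2) = var(e) − ψ′(df/2) (inverted by Newton iteration) and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the observed spread of
variances is no larger than chi-square sampling noise the estimate
degenerates to d₀ = ∞: complete pooling, normal-tail p-values. Moderated
p-values are two-sided; BH step-up adjustment; the DEG filter is strict
(`p_adj < 0.05` and `|log2FC| > 1.5`). No mean–variance trend is modeled:
the generator produces trend-free variances and the moderation scheme is
the plain exchangeable-prior one.

### Co-expression modules

Unsigned weighted network: genes with sample sd ≤ 0.5 are dropped, the
soft-threshold power β is scanned over 1…20, and for each power the
scale-free fit index (−sign(slope) · R² of the log–log degree-distribution
regression, ≤ 10 equal-width connectivity bins) and the mean connectivity
are recorded. β is the smallest power whose fit index reaches 0.85 among
powers whose mean connectivity stays ≥ 2; if no power reaches the target,
the conventional sample-size default for unsigned networks (β = 6 for
n ≥ 40 samples, larger for smaller n) is used instead of chasing the
argmax of the fit index. Two observations drove this design: raising the
power until the network is almost empty trivially improves the fit index
while destroying module structure, and on block-structured data the fit
index sequence is noisy enough that its argmax can land on powers of 2–3,
merging modules with noise.

Topological overlap is computed exactly from its definition
(TOMᵢⱼ = (Lᵢⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ)) via one matrix product, and
modules come from average-linkage clustering of 1 − TOM with a **static**
cut at 0.99 × the maximum merge height — a deliberate simplification of
dynamic tree cutting; the fraction is configurable (`cut_fraction`).
Clusters below 60 genes are labeled grey (unassigned). Modules take the
conventional size-ordered color names. Module eigengenes are the first
right singular vector of the gene-standardized module submatrix, oriented
so the mean correlation with module genes is positive. The trait is coded
Control = 0, Treat = 1; the key module maximizes |module–trait r| with
ties broken toward the larger module, and grey is never eligible.

### Gene-set funnel and benchmark

The hub set is the sorted three-way intersection of (up ∪ down) DEGs, the
key module's genes and the user-supplied mitochondrial list; matching is
exact string equality after whitespace trimming (upstream probe mapping is
assumed to have standardized symbols). All seven exclusive Venn regions
are reported.

The benchmark enumerates 113 configurations: 15 selector variants (Lasso;
Enet at α = 0.1…0.9; stepwise logistic both/backward/forward; glmBoost;
random forest) × 7 modelers (Ridge, SVM, LDA, naive Bayes, XGBoost, GBM,
PLS logistic) plus 8 standalone models (the 7 modelers and Lasso). The
manifest is an explicit, editable YAML structure; the shipped composition
is a design choice constrained by which algorithms have a meaningful
selection rule — penalized/boosted/stepwise fits drop zero-coefficient
variables, tree ensembles drop zero-importance variables, and SVM, LDA,
XGBoost and naive Bayes use all features (hence they never act as
selectors, and random forest — whose importances are rarely exactly zero —
is used only as a selector head, not duplicated as a pair member).

Per-algorithm conventions: penalized logistic fits choose λ at the
10-fold cross-validated deviance minimum over a 5-decade grid on
standardized features (CV-minimum, not 1-SE); stepwise fits are greedy
AIC descents stabilized by a vanishingly weak ridge (C = 1e6) so complete
separation stays finite; SVM uses an RBF kernel with cost 1, kernel width
1/p and Platt probability calibration; glmBoost is componentwise gradient
boosting of the logistic loss written in-package (step ν = 0.1, mstop by
10-fold CV up to 1000, refit at the optimum) — at large mstop on a single
covariate it reproduces the unpenalized logistic coefficient to better
than 2%; PLS logistic projects standardized features onto ≤ 5 components
chosen by 10-fold CV misclassification and back-projects the coefficients,
keeping features with |coefficient| > 1e-8; random forest uses 1000 trees;
GBM uses depth-2 trees, shrinkage 0.1 and the 10-fold cross-validated
best iteration up to 300 trees; XGBoost uses depth 6, η = 0.3, 5-fold CV
with early stopping after 25 rounds (cap 500).

A configuration whose selector keeps fewer than 2 features is recorded as
skipped rather than fitted degenerately. Ranking is by mean
validation-cohort AUC (reported as the C-index, which coincides with AUC
for a binary outcome) in descending order, ties broken by fewer selected
features and then label; the training-cohort AUC is reported separately
and never enters the ranking mean. Optional centering/scaling of the
feature block (off by default) provably leaves tree-based models'
rankings unchanged. Determinism: per-configuration seeds derive from a
CRC32 hash of the configuration label XOR the master seed; a selector's
seed derives from the *selector's* label alone so that one selector fit
can be shared by the seven configurations that reuse it — this caching
changes nothing statistically and saves most of the benchmark's runtime.

### Evaluation

AUC is the Mann–Whitney statistic computed from midranks (ties count one
half). The default interval is DeLong's variance estimator with a normal
95% interval clipped to [0, 1]; a seeded bootstrap percentile interval is
available and agrees with DeLong to ~0.02 at n = 100. Classification uses
a fixed 0.5 threshold with ties predicted positive (≥). Sensitivity,
specificity and accuracy are printed as percentages rounded half-up to
one decimal; raw fractions remain available from the counts.

## The synthetic-data generator

`simulate_cohorts` emulates the merged-cohort design:

    x_gj = μ_g + l_g f_{m(g),j} + δ·sign_g·1[Treat] ·1[g ∈ DE]
           + γ_{b,g} + ψ_b ε_gj

with gene baselines μ_g ~ U(4, 12) log2 units, module latent factors
f ~ N(0,1) per sample, loadings l_g ~ U(1.8, 2.5) for module genes (within-
module correlation ≈ 0.76–0.86) and 0 otherwise, batch shifts
γ ~ N(0, 0.5²) per gene per cohort, a cohort noise-scale ψ ~ U(0.8, 1.25),
and noise sd 1.0. Defaults: 3 + 3 cohorts of 15 controls + 25 cases, 2000
genes, module sizes (300, 150, 100, 80), 100 DE genes at δ = 2 (the filter
threshold of 1.5 sits 0.5 below the planted effect), a 15% mitochondrial
subset with 4-fold DE enrichment, and 80% of DE genes placed in the first
(largest) module so the DEG ∩ module ∩ mitochondrial funnel is non-empty
by construction.

Two deliberate choices make the construction well-posed rather than
luck-dependent:

* **DE genes inside the first module share one direction** (down in
  Treat, mirroring the depressed mitochondrial expression of tumors).
  Mixed signs would cancel in the module eigengene and leave the key
  module uncorrelated with the trait, emptying the funnel.
* **Module factors are orthogonalized to the group label** (mean-centered
  within each cohort × group cell). This is conditioning, not a model
  change — the factors are still N(0,1) per sample — but it removes the
  finite-sample factor–group imbalance (sd ≈ 0.19, amplified by loadings
  ≈ 2) that would otherwise shift every coherent module DE gene by the
  same random ±0.4 log2 units and let null modules reach |trait r| ≈ 0.2
  by luck. After centering, module–trait correlation arises only from
  planted differential expression.

Missingness is MCAR (the mechanism is a modeling choice; nothing in the
emulated design identifies it). The raw-intensity option emits 2^x so
that baselines in [4, 12] log2 units produce intensities whose q99
exceeds 100, exercising the log rule. Probe-level expansion adds a fixed
per-probe offset and can flag fractions of probes unmapped or ambiguous.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: platform-specific probe-affinity biases and
mean–variance trends, correlated (non-MCAR) missingness, outlier samples,
mixtures of tumor purity, non-normal heavy-tailed noise, and overlapping
or hierarchically merged modules. Results on this generator validate the
*implementation* of each stage and the *logic* of the funnel, not the
biology of any particular cohort.

## Problem sizes and reproducibility

The shipped defaults (2000 genes, 120 training samples, 113
configurations on a few dozen hub genes) keep a full discovery run in the
minutes range on a single CPU while leaving every stage's statistical
behaviour measurable; they are scaled-down analogues of a realistic
multi-cohort study (~15–20k genes), chosen as the package's reference
conditions. All randomness flows from one master seed through CRC32-based
per-stage derivation, so stages can be re-run in isolation and full runs
are bit-reproducible; `scripts/acceptance.py --seed N` re-executes the
entire chain from scratch.

## Known limitations

* Static tree cut instead of dynamic hybrid cutting; nested or unbalanced
  module structures may fragment at the fixed cut height.
* No RMA: the pipeline starts from processed expression matrices, not CEL
  files.
* No module merging by eigengene correlation and no block-wise
  decomposition for very large gene sets.
* Stepwise selection is greedy (single best move per round) and can stop
  at a local AIC minimum, as all stepwise procedures do.
* The C-index equals mean validation AUC only because the outcome is
  binary; no survival analysis is implemented.
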