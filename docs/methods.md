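# Methods

`neuralpcos` implements a two-class transcriptomic diagnostic-score pipeline:
differential-expression screening, annotation-based enrichment, random-forest
gene selection, neural-network weight derivation, a linear per-sample score,
and ROC validation. This note records the statistical models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
data do and do not establish.

## Pipeline model

**Differential expression.** Each gene is fitted with a pooled two-group
linear model on log2-scale expression: logFC = mean(case) − mean(control),
residual variance s²_g on d_g = n₁ + n₂ − 2 df. Gene variances are assumed
exchangeable with a scaled-inverse-χ² prior (d₀, s₀²); the hyperparameters
are estimated by closed-form moment matching on log s²_g (digamma/trigamma
identities, Newton inversion of the trigamma function). The posterior
variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) gives the moderated statistic
t = logFC / (s̃_g √(1/n₁ + 1/n₂)) on d₀ + d_g df. This is the standard
empirical-Bayes treatment for microarray linear models; the implementation
agrees with R `limma::eBayes` to machine precision on shared fixtures
(tested). DEG status requires raw p < 0.01, |logFC| > 0.26, and average
expression above the bottom 25% of all genes. Raw p (not BH-adjusted) drives
the call; the adjusted values are reported and the BH adjustment is reserved
for enrichment. The low-expression filter is applied after the p/logFC cut,
and both pre- and post-filter counts are reported, because the two stages of
counting are meaningful separately.

**Batch adjustment.** The location/scale empirical-Bayes model: per gene,
a standardization fit with batch means and a protected class covariate;
per-batch location (γ) and scale (δ²) estimated on standardized residuals
and shrunk toward moment-matched priors — Normal for γ, inverse-gamma for δ²
— by iterated conditional modes to relative tolerance 1e-4. A non-parametric
variant (`parametric=False`) replaces the parametric posterior with weighted
Monte-Carlo posterior means over the other genes' estimates (leave-one-out).
The parametric mode agrees with `scanpy.pp.combat` to ~1e-5 (tested). Genes
with zero pooled variance pass through unadjusted; a batch with a single
sample is rejected. Note that even with no true batch effect the adjustment
moves values at the noise scale of the per-batch estimates (≈0.1 at 20
samples/batch with residual sd 0.2); this is inherent to the estimator, not
an artifact of this implementation.

**Enrichment.** Hypergeometric upper tail P(X ≥ k) for k DEG members of a
K-gene term in an N-gene universe with n DEGs, BH-adjusted across terms.
The per-term z-score is (n_up − n_down)/√k (0 when k = 0), the bubble-plot
direction-balance convention. Redundant terms are pruned greedily: visit
significant terms by (adj_p, term size, term id) and drop any term whose
DEG-member overlap with an already-kept term exceeds 75% of the smaller
member set. Greedy keep guarantees the surviving set is overlap-free and a
re-run is a no-op; purely pairwise marking does not. The overlap rule is
applied pairwise on DEG members with the smaller term as denominator — the
procedure's description admits several readings and this one keeps the most
significant representative of each redundancy cluster.

**Random forest.** Explicit bagging over CART (Gini) trees with per-sample
bootstrap counts, so out-of-bag (OOB) bookkeeping is exact and open:

* *mtry tuning*: every mtry from 1 to min(mtry_max = 2000, #genes) is probed
  with a 500-tree forest; chosen mtry is the OOB-error argmin, ties to the
  smallest (cheapest) value.
* *ntree tuning*: the cumulative OOB error trace up to ntree_max = 3000 is
  recorded; chosen ntree is the earliest tree count from which the trace
  stays within ε = 0.005 of its minimum ("lowest error with stability").
  If the trace never settles in the band, the argmin is used.
* *importances*: MeanDecreaseGini is the raw total Gini-impurity decrease
  (node bootstrap counts × impurity drop, summed over splits, averaged over
  trees) — the unnormalized convention under which an absolute threshold of
  0.15 is meaningful; a normalized (sum-to-one) variant is available.
  MeanDecreaseAccuracy is true per-tree OOB permutation importance: the drop
  in a tree's OOB accuracy when one feature's OOB values are permuted,
  averaged over trees.
* Genes at MeanDecreaseGini ≥ 0.15 are selected, ranked descending. An empty
  selection warns rather than raises.
* Because the tuned ntree can legitimately be very small on separable data
  (the trace reaches zero immediately), the forest used for *importance* gets
  a floor of 500 trees; importance averaged over one tree is degenerate.

**Network and score.** The selected genes are min-max normalized per gene
(x′ = (x − min)/(max − min), training ranges stored; constant genes map to
0.5). A d–3–2 feed-forward network — logistic activations on the hidden and
both output units, outputs one-hot coding control/case — is trained
full-batch against a sum-of-squared-error loss with resilient
backpropagation (iRprop−: per-weight step sizes multiplied by 1.2/0.5 on
gradient sign agreement/flip, steps in [1e-6, 50], initial 0.1), weights
initialized Normal(0, 0.5²), until the largest gradient magnitude falls
below 0.01 or 1e5 epochs. Training tracks the best-so-far weights, so the
recorded error trace is non-increasing and the returned model is never worse
than its initialization (Rprop's raw epoch-to-epoch error is not monotone).

The per-gene weight is the network's linearized class-discriminative
contribution, w_g = Σ_h W1[g,h]·(W2[h,case] − W2[h,control]); it is exact
under linear activations, per-gene rather than per-sample, and invariant to
hidden-unit permutation. The raw W1/W2 matrices are exported in the model
provenance so alternative extraction rules can be applied post hoc. The
diagnostic score of a sample is then the plain linear functional

    score(x) = Σ_g x_norm[g] · w_g ,

with validation expression normalized by the *training* min/max (clipped to
[0,1]) — reusing training ranges avoids information leakage; recomputing on
validation data is available by flag.

**Evaluation.** ROC thresholds sweep the unique score values (±∞ endpoints);
a sample is called positive when score ≥ threshold. AUC is the trapezoidal
area and equals the Mann–Whitney all-pairs concordance (ties 0.5; tested to
1e-12). The reported operating point maximizes Youden's J, ties resolved to
the lower threshold. Comparator panels (e.g. the built-in endometrial
insulin-pathway trio IGF1/PTEN/IGFBP1 and the granulosa steroidogenesis
quartet HSD3B2/STAR/INHBA/CYP19A1) are scored as the unweighted sum of
min-max-normalized expression — the all-weights-one analogue of the neural
score, the minimal rule consistent with a panel of upregulated markers.
Scores are not auto-flipped when AUC < 0.5; orientation honesty is the
default.

## Synthetic data

The generator emulates the inputs the pipeline consumes, so every stage is
testable without downloads:

* Gene baselines μ_g ~ Normal(7, 1.5²) log2 units — a typical microarray
  intensity range that makes the bottom-quantile expression filter
  meaningful.
* Gene variances σ²_g ~ scaled-inv-χ²(d₀ = 10, s₀² = 0.04): residual sds
  concentrated near 0.2 log2 units, typical of good-quality arrays, and the
  same hierarchical form the moderated-t prior assumes, so prior recovery is
  itself testable (the moment estimates land near (10, 0.04) on large
  simulations).
* Planted DE genes (default 50 of 2000, |logFC| = 2, half up/half down) are
  drawn from baselines above the median: detectable differential signal in
  real studies arises among expressed genes, and planting it in the noise
  floor that the low-expression filter exists to discard would make the
  ground truth incoherent.
* Batches add gene-wise Normal(0, batch_shift_sd²) offsets; samples are
  assigned round-robin within each class so batch and class stay balanced.
* RNA-seq mode emits negative-binomial counts (gamma-Poisson with dispersion
  α = 0.1, mean 2^signal − 1) and leaves the log2(CPM+1) transform to the
  preprocessing stage, keeping raw counts available.
* Annotations are random 10–200-gene terms; designated enriched terms draw a
  configurable fraction of members from the planted DE set.
* A validation cohort can be drawn from the same study (same genes,
  baselines, variances, and planted truth; fresh sample-level randomness)
  with `simulate_validation`.

What the generator does **not** emulate: probe-level artifacts, intensity-
dependent variance trends, correlated gene modules, platform shifts between
training and validation cohorts, library-size or GC biases in counts, and
ontology DAG structure. Passing tests therefore demonstrate that the
implementation recovers what it is mathematically supposed to recover under
its own model assumptions — not that the score generalizes across real
platforms or cohorts.

## Numerical choices and degenerate inputs

* Counts transform: log2(CPM + 1) — the minimal-assumption standard when no
  transform is prescribed; zero counts map to exactly 0.
* TSV round trip is bit-exact (`float_precision="round_trip"` on read).
* BH adjustment uses the textbook sort / p·m/rank / cumulative-minimum
  formula so it is bitwise equal to the brute-force definition.
* Constant genes: min-max maps them to 0.5; both forest importances are 0;
  the moderated t is 0 with p = 1 when groups are identical.
* One global pipeline seed expands into per-stage seeds by hashing the stage
  name (SHA-256, reduced below 2³¹), so stages are independently
  reproducible and two runs of the same config are byte-identical.
* Tie-breaks are all deterministic: smallest mtry, lower ROC threshold,
  first class on OOB vote ties, (adj_p, size, id) ordering in pruning.

## Problem sizes

Tests and the acceptance script run the pipeline at 2000 genes, 50 planted
DE genes, 20 cases vs 20 controls, averaged over three replicate seeds —
comparable to the screening cohort sizes the procedure targets, and large
enough that calibration fractions and recovery rates are stable at the
tolerances asserted.

## Known limitations

* The mtry loop refits a probe forest per value; with thousands of input
  genes this is the dominant cost (the loop is bounded by mtry_max).
* The non-parametric batch-adjustment posterior is O(genes²·samples) per
  batch; it is intended for the moderate gene counts that follow screening.
* Network training is unregularized by design (mirroring the reference
  procedure): on separable data weights grow until the gradient criterion
  halts them, so weight *magnitudes* are not interpretable — only their
  signs and relative sizes feed the score, and AUC is invariant to scale.
* No cross-validation or model selection is performed; the training/
  validation split is the only generalization check, as in the reference
  design.
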