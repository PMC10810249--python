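# Methods

## Problem setting

Given a log2-scale expression matrix (genes × samples, RMA-like), binary
class labels (cancer = positive, normal = negative) and optionally batch
labels, the package selects a gene subset that supports accurate
classification while penalizing subset size, and reports a held-out
evaluation of the selection.  All randomness is driven by explicit seeds;
every run is exactly reproducible.

## Pipeline stages

### Loading and probe collapsing (`io_prep`)

Probes mapping to the same gene symbol are collapsed by the per-sample
arithmetic mean; unmapped probes are dropped with a logged count.  Collapsed
genes are ordered lexicographically so output is independent of probe order.
"Unexpressed" features have no canonical definition on the RMA scale (there
are no zeros), so two filters are offered and logged: zero-variance removal
(default) and an all-below-threshold mode.

### Cohort merging and batch adjustment (`batch_merge`)

Cohorts are concatenated on the **intersection** of their gene sets (a
union would create missingness downstream stages cannot represent).  Batch
effects are removed with the standard parametric empirical-Bayes
location/scale model: per-gene standardization against a batch-size-weighted
grand mean and pooled variance, method-of-moments hyperpriors
(normal for locations, inverse-gamma for scales), fixed-point joint
posterior modes, then removal of the shrunk batch terms.  The class label
enters the standardization design as a centered covariate by default
(`use_labels=False` disables it) so class-composition differences between
batches are not absorbed into the batch term.  A two-component PCA
diagnostic quantifies batch separation before/after.

Numerical notes: the adjustment is *not* exactly idempotent — a second pass
still shrinks per-batch scales toward the prior, changing values at the
~1e-3 level on typical simulated data, far below the noise scale.  Variances
are floored at 1e-12; a single-batch input is returned unchanged.

### Differential expression (`dge`)

A gene is a DEG when |log2 fold change| > 2 (difference of class means on
the log2 scale) **and** Benjamini–Hochberg adjusted p < 0.05.  The default
test is Welch's unequal-variance t; a moderated t with empirical-Bayes
variance shrinkage (log-scale moment matching of the scaled-F model, the
limma approach) is available and agrees with `limma::eBayes` to ~1e-14 on
shared fixtures.  Zero-variance genes yield t = 0, p = 1.

### The fitness oracle (`objective`)

* Stratified 60/20/20 split; per-class counts are floors of the fractions
  with remainders handed out train → validation → test, so every partition
  holds both classes and per-class proportions are within one sample of the
  targets.
* SMOTE balances the **training partition only**.  Each synthetic point is
  `x + u·(x_nn − x)`, `u ~ U(0,1)`, between a minority sample and one of
  its k = 5 minority nearest neighbors (k capped at minority − 1).
  Resampling happens **once per run** (seeded), in the full feature space;
  masks then subset columns.  This makes fitness a pure deterministic
  function of the mask (enabling caching by mask bytes) at the cost of not
  re-estimating neighbor geometry inside each candidate subspace.
* Base learners (fixed, logged): gradient-boosted trees (15 trees, depth 2,
  √-feature subsampling), RBF-SVM (C = 1), random forest (12 trees,
  depth 6), decision tree (depth 6).  These are deliberately small: the
  training partitions are ~10² samples and one selection run makes ~7·10³
  fitness evaluations, so larger models would add variance and cost without
  more signal.
* Classifier weights are normalized products of the five validation metrics
  Ac·Pr·Re·F1·F2 (uniform fallback, flagged, if all products vanish).
  Metrics with zero denominators are reported as 0 and flagged rather than
  propagating NaN into the products.
* Weighted hard voting; ties resolve to the positive (cancer) class — the
  conservative choice for a screening objective.
* Fitness (minimized): `φ·(1 − Avg_Eclf) + (1 − φ)·NF/AF` with φ = 0.8.
  The literal maximized form `φ·Avg + (1 − φ)·NF/AF` is exposed via
  `literal=True`, but as a maximization it rewards *more* features and is
  inconsistent with reported fitness values near 0.05 at ~13% feature
  density; the minimized complement reproduces those values exactly (e.g.
  Avg 0.978, NF 1404, AF 10629 → 0.0440) and is the default.
* An empty mask scores the sentinel worst fitness 1.0 without training.

### The optimizer (`bgwo`, `sa_refine`, `pipeline`)

The binary grey-wolf update follows the sigmoid-transfer/binary-step
equations exactly (see README).  Draw granularity, which the equations do
not pin down, is: fresh per-dimension `r1`, `r2` per leader; one `r3` per
dimension shared by the three binary-step comparisons; one `r4` per
dimension for the crossover.  Leaders are re-ranked after every sweep, ties
broken by fewer selected features, then wolf index.  The best-so-far mask is
recorded separately from the leader set, so the reported trace is
non-increasing by construction.

Simulated annealing refines the alpha mask at the end of every iteration:
geometric temperature ladder (T0 = 0.1, factor 0.9, floor 1e-3 — sized so
typical fitness deltas of 0.01–0.1 are occasionally accepted early and
frozen late), 5 proposals per level, operator chosen by roulette wheel.
All five operators conserve the number of selected features — annealing
explores *arrangements* at fixed NF.  An optional bit-flip operator (off by
default) lifts that restriction.  The refined mask replaces alpha only if
not worse, preserving the monotone trace.

A structural property worth knowing: the update rule anchors candidate bits
as `X_L OR bstep`, so a leader's 1-bits always propagate into candidates.
Consequently the optimizer cannot *reduce* NF against a flat error surface
(mask density is non-decreasing in expectation), and when the data are so
cleanly separable that every visited mask classifies the validation
partition perfectly (`Avg ≡ 1`), the fitness degenerates to the NF penalty
and carries no per-gene information.  In that regime the selected set is
not enriched for truly informative genes.  When the error term is
informative (weaker effects, or a surrogate that rewards specific bits),
the optimizer recovers planted features essentially completely — the test
suite demonstrates both regimes.

Baselines: the annealing-free ablation (`use_sa=False`); a generational GA
over the same fitness (tournament size 3, uniform crossover p = 0.5,
bit-flip rate 1/AF, one elite — standard defaults, all configurable); a
Monte-Carlo filter ranking (random feature subsets scored by
cross-validated random-forest F1, each member credited with subset-F1
weighted by within-subset importance) followed by incremental prefix search
in steps of 5 (ties prefer the smaller prefix); and an L1-logistic LASSO
exposed through the CLI via scikit-learn, not reimplemented.

### Held-out evaluation and superior genes

The final mask is evaluated by six classifiers (gradient-boosted trees,
decision tree, random forest, SVM, k-NN, small MLP) trained on
train ∪ validation (SMOTE-balanced train) and scored on the untouched test
partition: per-classifier and mean F1, PR-AUC, ROC-AUC, MCC and balanced
accuracy, with scores taken from `predict_proba` or `decision_function`.
"Superior genes" are the exact intersection of all supplied DEG sets and
selected sets.

## Synthetic data

The generator emulates processed two-class microarray data: Gaussian noise
(σ = 0.5) around a log2 baseline of 7, a planted set of informative genes
with mean shift 2.5 (random sign, so both directions occur), positive-class
fraction 0.8 (≈4:1 imbalance, matching typical case-control cohorts of this
kind), and an optional two-batch mode with per-gene additive offsets
(sd 1.0) and multiplicative noise-scale spread.  It does **not** model
probe-level artifacts or gene-gene correlation, so green tests establish
correctness of the machinery and behavior under independent-gene Gaussian
data, not performance under realistic co-expression structure.  At the
default effect size the classification problem is (intentionally) easy;
tests that need an informative error surface use weaker effects and say so.

## Known limitations

* The annealing stage cannot change the selected-feature count (operator
  set conserves popcount) — by design, with an opt-in bit-flip escape.
* Wrapper selection pressure vanishes on perfectly separable data (see
  above); enrichment claims should always be checked against a planted
  ground truth or permutation null.
* The empirical-Bayes adjustment is the parametric variant only.
* SMOTE neighbor geometry is computed once in the full feature space, not
  per candidate subset.
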