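# Methods

This note documents the models and procedures `bicpred` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical and design choices made where the design
was genuinely open.

## Problem setting

The prediction target is iPET2: the result of an interim FDG-PET scan
after two courses of ABVD chemotherapy in Classical Hodgkin's Lymphoma,
binarized on the Deauville scale (positive iff ≥ 4, i.e. refractory).
Inputs are diagnostic-sample expression profiles over a targeted panel
(hundreds of genes, normalized counts) and four clinical covariates:
age (years), gender, Lugano stage, and the dichotomized
lymphocyte-to-monocyte ratio LMR > 2.1. Cohorts of this kind are small
(~100 samples) and imbalanced (~80% negatives), expression is
heavy-tailed with frequent outliers, and most genes individually carry
little signal — the regime every design choice below answers to.

## Preprocessing

- Expression is log2 transformed with a configurable pseudocount
  (default 1, since normalized counts can fall below 1; `log2(x + 1)`
  keeps the transform non-negative and invertible). A flag on the
  cohort forbids accidental double transformation.
- Samples with any missing expression, clinical, or outcome cell are
  removed; the operation is idempotent and logs the removal count.
- Lugano stage is encoded ordinally, I A < I B < … < IV B → 1…8: both a
  higher numeral and the B variant are worse prognostic factors, so the
  code order is prognostically monotone.
- Gender and LMR > 2.1 are coded {0, 1} (see `bicpred.cohort.GENDER_CODES`);
  the coding is arbitrary but fixed package-wide so fitted models are
  portable.
- Clinical covariates are appended to the gene matrix for feature
  selection: stage and LMR > 2.1 are plausible outcome correlates and
  should compete with genes in the univariate screen.

## Two-phase feature selection

Most genes fail Shapiro–Wilk normality (the `normality_screen` operation
quantifies this per cohort), so phase 1 uses distribution-free tests:

- **Wilcoxon rank-sum**, two-sided, per feature, testing whether the
  class-conditional distributions differ. Exact enumeration is used when
  both classes have ≤ 8 samples and no ties; otherwise the tie-corrected
  normal approximation (no continuity correction, so identical class
  multisets give p = 1 exactly).
- **Mutual information** between each feature and the outcome, estimated
  with the k-nearest-neighbor estimator (k = 3) on *rank-transformed*
  features. MI is invariant under strictly monotone transforms; ranking
  makes the estimate (and the p-value) exactly so. Significance comes
  from a one-sided permutation test with the add-one convention,
  p = (1 + #{MI_perm ≥ MI_obs}) / (1 + n_perm), n_perm = 999 by default,
  so p can never be zero.

The two p-values are combined at a deliberately loose α = 0.1 with a
**union** rule (retained if either test is significant). The screen's
purpose is to avoid discarding potentially relevant genes, and the union
is the permissive reading; an intersection mode is available by flag.

Phase 2 is **SVM-RFE**: a linear soft-margin SVM (C = 1) is fit on
standardized survivors, features are ranked by squared weight, and the
lowest `max(1, ceil(0.1 · current))` are removed per round until 14
remain (both knobs configurable). C, the standardization, and the step
rule are this package's documented defaults, not inferred from elsewhere.
Clinical covariates pass through phase 1 but are excluded from RFE by
default so the final signature is genes-only (flag to include).

## Discriminative pattern-based biclustering

A *bicluster* is a set of genes each pinned to one discrete expression
level, together with the exact set of samples exhibiting those levels —
a putative regulatory module with a coherent expression pattern.

- **Discretization**: per-gene equal-frequency binning into L labels
  (default 10), robust to heavy tails. Ties at a bin edge go to the
  lower label. A gene with fewer distinct values than L is binned on its
  distinct values with a warning. Bin edges are stored so held-out
  samples can be labelled with the *training* edges.
- **Mining**: all closed frequent itemsets over items `(gene = label)`
  with support ≥ `min_support` (default `ceil(0.1 n)`) and ≥ `min_genes`
  (default 3) items, by depth-first prefix-preserving closure extension.
  Closedness bounds the output without losing any (pattern, support)
  pair; the miner is validated against brute-force enumeration on small
  random matrices, including masked cells.
- **Lift**: `lift(B) = max_c P(z = c | rows(B)) / P(z = c)` — the
  standard association-rule lift against class consequents. It is ≥ 1,
  bounded by `1 / min(prevalence, 1 − prevalence)`, and attains the bound
  only on pure-class supports.
- **Masking iterations**: biclusters with lift ≥ `min_lift` (default
  1.3) are kept and their cells masked (masked cells support no item —
  simpler and deterministic compared with random-value replacement);
  mining repeats up to `n_iterations` (default 9) times or until an
  iteration keeps nothing. A kept bicluster can never be re-found: all
  of its supporting cells are masked.
- **Output**: sorted by (lift desc, area desc, gene ids) — a total order
  that makes top-k truncation (default 250) reproducible — and packaged
  with the fitted bin edges. The module is deterministic end to end.

Defaults (9 iterations, min lift 1.3, 10 labels, 250 biclusters) follow
the parameterization used for the study-scale analysis.

**Choosing L.** With single-label discretization, a coherent module is
only minable if its carriers share a bin, so the expected carrier count
should not exceed one bin's mass n/L; coarser labelings (L = 3–5) are
appropriate for modules expected in ~20% of ~100 samples, while L = 10
discriminates finer levels when patterns need not capture an entire
carrier group. (Fuzzy multi-label "overlapping" discretization would
relax this constraint; it is out of scope here, and each cell receives
exactly one label.)

## Pattern-centric space transformation

Each bicluster becomes one feature. The per-gene *expected value* of a
pattern is the training-support centroid (mean expression over
supporting rows) rather than a bin midpoint — the centroid preserves
within-bin information; a bin-midpoint mode is available by flag.

- **Euclidean criterion**: `value(i, B) = sqrt(Σ_j (x_ij − e_Bj)²)` over
  the genes of B; 0 iff the sample matches the expectation exactly. Raw
  by default; a `normalize` flag divides by `sqrt(|genes|)` to compare
  biclusters of different sizes.
- **Binary criterion**: 1 iff every gene's label (computed with the
  training bin edges) is within `tolerance` labels of the pattern.
  Matrices are pointwise monotone in the tolerance. With integer labels
  a fractional tolerance below 1 (e.g. 0.5) admits exact matches only —
  retained for interface fidelity and documented as equivalent to 0.

Everything — edges, supports, expectations, lifts — is fitted on
training data and applied unchanged to held-out samples.

## Evaluation

- **Setting II (sound)**: stratified nested CV, 10 outer folds by
  default. Stratification is a design choice forced by arithmetic: with
  21 positives and 10 folds, unstratified folds can lack positives and
  leave recall undefined. Inside each outer-training fold: optional
  selection, optional pattern transformation, per-feature
  standardization, SVM-SMOTE balancing, and a TPE hyperparameter search
  over 5 inner folds (default budget 50 trials) maximizing F1 — chosen
  so tuning is sensitive to the minority class. The outer-test fold only
  passes through fitted objects; `fit_outer_fold` is exposed separately
  so the guard is directly testable (perturbing held-out samples changes
  no fitted fingerprint).
- **Setting I (optimistic)**: feature selection and tuning once on the
  full cohort, then bootstrap resampling (default B = 100; in-bag train,
  out-of-bag evaluate). Kept for comparison with selection-then-validate
  protocols; every output is tagged `optimistic=True`.
- **SVM-SMOTE**: minority oversampling to parity seeded at minority
  support vectors of an RBF SVM (the borderline region), each synthetic
  sample a convex combination of two original minority samples; applied
  to training data only. In pattern-space runs balancing happens *after*
  the transformation (in pattern space), configurable.
- **TPE**: after `n_init` random trials, observed trials are split at
  the γ = 0.25 quantile; each parameter is modelled by Parzen densities
  (Gaussian kernels with Scott-like bandwidth, floored at 1/25 of the
  span, plus a 5% uniform component that keeps density ratios finite; a
  smoothed count ratio for categorical parameters), and the candidate
  maximizing the good/bad density ratio is evaluated next. Deterministic
  given the seed.
- **Metrics**: AUC from the tie-corrected Mann–Whitney rank statistic
  (cross-checked against brute-force concordant-pair counting in tests);
  precision, recall, specificity, F1 at a fixed 0.5 threshold (undefined
  ratios reported as 0 and flagged); precision–recall curves expose
  threshold sensitivity. A random-classifier baseline (fair-coin labels
  for threshold metrics, uniform scores for AUC, 20 iterations) provides
  the reference floor: precision ≈ prevalence, everything else ≈ 0.5.
  Misclassification structure is reported per clinical stratum (gender,
  LMR > 2.1, stage, decade age bins) with small strata suppressed.

## Synthetic cohorts

The generator emulates the features the method must survive:

- log2-scale background expression with per-gene means ~ N(8, 2) and
  per-gene SDs log-uniform on [0.5, 2] (strong between-gene variability);
- outlier cells (default 1%) replaced by mean ± 6 SD draws (heavy tails);
- a stratified imbalanced outcome: exactly `round(prevalence · n)`
  positives for every seed (default prevalence 0.204, the study's
  post-preprocessing balance), never Bernoulli, so class counts cannot
  flake;
- independent clinical covariates (age uniform 15–70, fair-coin gender
  and LMR, uniform stage);
- **planted biclusters**: for each module, a `penetrance` fraction of
  the enriched class is redrawn ~ N(pattern level, noise_sd) over the
  module's genes. Levels are either explicit or offset from the gene's
  own background by `level_shift_sd` SDs: a large shift (≈ 4) plants a
  clearly upregulated module; a shift of 0 plants a *mid-range coherent*
  module whose genes are individually almost uninformative while the
  joint pattern is strongly discriminative — the scenario the
  pattern-space transformation exists for. Carrier sets are recorded as
  ground truth.

All randomness flows from one seeded generator; cohorts are bitwise
reproducible. Not emulated: count-level (pre-log) noise, probe
chemistry, batch effects, correlated backgrounds, or covariates that
correlate with outcome — so passing tests demonstrate correctness and
calibration of the machinery under the stated structure, not clinical
performance on real cohorts.

## Problem sizes in the test suite

Test and acceptance runs use study-scale or smaller cohorts chosen as
the smallest sizes at which each property is identifiable: 103 × 200
for planted-module recovery (one 10-gene module, penetrance 1,
noise 0.05, mined at L = 5 per the bin-mass rule above), 103 × 60–80 for
null calibration, 90 × 60 with two mid-range 8-gene modules (penetrance
0.9, mined at L = 3, support floor 13 ≈ the expected module size) for
the decision-tree pattern-space uplift, and 60 × 150 weak-signal cohorts
for the setting I/II optimism gap. Stochastic checks always average over
≥ 8–10 seeds and compare means, never single runs.

## Known limitations

- Constant-value pattern coherence only; additive, multiplicative and
  order-preserving coherence, noise-relaxed supports, and fuzzy
  multi-label discretization are not implemented.
- Lift is the only bicluster filter; no statistical-significance
  p-values are attached to biclusters.
- The nested-CV harness refits selection/transformation once per outer
  fold (hyperparameters alone are tuned in the inner loop), which is the
  protocol's stated contract but leaves inner-loop selection variance
  unexplored.
- With ~21 positives, per-fold recall/precision are quantized in steps
  of 1/2–1/3; aggregate means over folds inherit that granularity.
- KNN's probability estimates make its 0.5-threshold metrics fragile;
  PR curves are the better lens for it.
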