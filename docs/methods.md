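# Methods

This note records the statistical model behind `radclass`, the choices made
where the procedure left room, and what the synthetic cohort does and does
not establish about real data.

## Synthetic cohort model

Real radiomics tables exhibit heavy redundancy (texture features computed
from the same matrices correlate strongly), skewed marginals, occasional
missingness, and degenerate columns.  The generator reproduces these traits
with a Gaussian latent-factor model chosen for analytic tractability: for
modality m and cluster c, each patient i draws a latent factor
z_i ~ N(δ_c(class_i), 1), and each of the cluster's features is

    x_ij = λ · z_i + √(1 − λ²) · ε_ij,    ε_ij ~ N(0, 1) i.i.d.

so every feature has unit variance, the expected within-cluster Pearson
correlation is exactly λ², and between-cluster correlation is 0.  Class
signal enters only through the per-cluster latent mean shift δ_c, expressed
in latent-SD units; on the feature scale the induced mean separation is λδ.

Key parameters (defaults in parentheses):

- `class_counts` — patients per (origin, histology) cell; the reference
  config carries the 391-patient composition: GE 76 AC / 52 SCC, H&N
  2 AC / 119 SCC, pulmonary 94 AC / 48 SCC.  Labels hit these counts
  exactly; only their order is randomised.
- `within_cluster_loading` λ (0.8) — redundancy strength; 0.8 gives
  within-cluster r ≈ 0.64, strong but not degenerate redundancy.
- `n_clusters_per_modality` (15) × `features_per_cluster` (10) — 150
  features per modality, a realistic order of magnitude for a curated
  radiomics panel and enough for the 15-cluster cut to be meaningful.
- `effect_sizes` — the reference default plants moderate histology signal
  in two CT clusters (δ = 0.8 and 0.6), origin signal in two more CT
  clusters, and weaker PET signal (δ = 0.4–0.5), mirroring the qualitative
  pattern that CT features carry most of the discriminative information.
  Recovery tests override this with three δ = 1.5 clusters.
- `skewed_fraction` (0.2) — these columns are exponentiated, which for a
  unit-variance Gaussian input forces mean/median > 1.5 and so exercises
  the log branch of the transform rule; a quarter of them
  (`signed_skew_fraction`) are shifted down by 0.5 so they cross zero and
  exercise the signed-sqrt branch instead.
- `missing_features` — MCAR missingness at per-feature rates.  The
  reference rates (0.22–0.40) all exceed the 20% QC cut-off, so after QC no
  missing data remain, matching the cohort the defaults emulate.  The
  missingness mechanism of real tables is unknown; MCAR is the neutral
  choice and nothing downstream models the mechanism.
- `n_constant_features` (2) — zero-variance columns for the QC filter.

One seed drives a per-purpose `SeedSequence` (labels, factors, noise, skew
placement, missingness, constants), so regeneration is bit-identical and
each component is independently reproducible.

What passing tests on this cohort do **not** show: robustness to
non-Gaussian dependence (real texture features are nonlinearly related),
informative missingness, scanner batch effects, or calibration of the
logistic probabilities on real populations.  The generator validates the
machinery and its operating characteristics under a known truth, not
clinical performance.

## Preprocessing decisions

- **Normalization for clustering.**  The data-dependent normalizer is the
  rank-based inverse-normal (ordered-quantile) transform,
  Φ⁻¹((rank − ½)/n) with mean ranks for ties.  Its output feeds only the
  clustering distance; models are fitted on the data-independent log /
  signed-sqrt scale, whose fitted per-feature rule transfers unchanged to
  unseen data.
- **Clustering distance.**  1 − |Pearson r| on the normalized training
  values, complete linkage, tree cut at exactly k = 15 clusters per
  modality.  The absolute value makes grouping invariant to sign flips —
  a feature and its negation are perfectly redundant for classification.
- **Mean/median ratio** is computed on raw (pre-normalization) training
  values with the arithmetic mean and sample median; a zero median leaves
  the ratio undefined and the feature untransformed (with a warning).
  Natural log is used.
- **Residual missingness** after QC is an error rather than silently
  imputed, because the pipeline's contract is a complete post-QC table; a
  `--impute-median` escape hatch exists but is off by default.

## Screening and model fitting

- The variance-explained screen R² is the squared point-biserial
  correlation.  Ties in |r| or p are broken by lexicographic feature name,
  so selection never depends on column order.
- The Kruskal–Wallis screen is used for the partitioning route at any
  number of outcome levels; with two groups it is the 1-df rank test.
- **APS**: each subset's logistic fit carries a tiny ridge penalty (1e−6 on
  the coefficients) so perfectly separating subsets — guaranteed to occur
  during exhaustive enumeration — stay finite; the Youden-based selection
  is insensitive to a penalty of this size.  The decision threshold is the
  train-ROC Youden-optimal cut, ties to the lower cut.  Enumeration refuses
  more than 2²⁰ subsets; with ≤15 representatives per modality (≤30
  combined) this cap is never reached in normal use.
- **Model selection is in-sample**: the winning subset (by training Youden)
  and the winning tree depth (by training κ) are chosen on the training
  split and then evaluated once on the held-out split.  There is no inner
  cross-validation; this follows the procedure's per-replicate
  train-then-test discipline, and the repeated-split distribution is what
  absorbs the optimism.
- **Random forest / CART settings** (unspecified by the procedure, fixed
  here): 500 trees, √k features per split, permutation importance with 5
  repeats on the training data; CART with Gini impurity, minimum leaf 5,
  max depth = number of features entered; everything seeded per replicate.
- **Fallbacks**: if no feature passes a screen, the replicate's model for
  that method/modality degrades to the prevalence model and the record is
  flagged (`fallback=True`).
- The positive class for binary metrics and the AUC is a configuration
  parameter (default SCC), not an assumption: the two modelling routes can
  legitimately be reported with different positive classes.

## Cross-validation and summaries

- Splits are simple random (unstratified) with train size
  round(train_fraction × n), 313/78 at the reference size; a stratified
  mode exists for sensitivity analysis.  All randomness flows from one
  master seed through named substreams (split, model seeds, prevalence
  draws), and each replicate's seed is logged, so any replicate can be
  regenerated bit-for-bit from the replay log.
- Metrics for multi-level outcomes are one-vs-rest per class.  For the
  combined origin×histology task the model trains on all six classes but
  reports only those with at least 5 expected held-out members (five
  classes at the reference composition — the H&N-AC cell, n = 2, is
  trained on but not reported); the floor is configurable.
- Undefined cells (e.g. sensitivity when a rare class is absent from a
  78-patient test set) are dropped and counted, never imputed as zero;
  summaries report the number of usable replicates per cell.
- Summary statistics are the median and the 2.5th/97.5th percentiles with
  linear interpolation between order statistics.
- The prevalence benchmark's operating point is analytic: with positive
  prevalence p, E[sens] = p, E[spec] = 1 − p, E[J] = 0, and the
  central-95% width of one-vs-rest sensitivity tracks the binomial
  approximation 2·1.96·√(p(1−p)/n_class,test).  The acceptance script
  recomputes these cells by simulation at the reference composition.

## Problem sizes used in checks

The package's own test suite runs the chance benchmark at the full
1000-replicate reference scale (it needs labels only and is cheap), the
planted-signal recovery and partitioning-vs-benchmark comparison at 100
replicates on a 391-patient cohort, and the brute-force equivalence of the
subset search at ≤4 candidate features over 50 random datasets — sizes
chosen so each check is decisive for the property it tests while the whole
suite stays desk-scale.

## Known limitations

- APS is exponential in the number of representatives; it is practical at
  k ≤ 20 and intended for the ≤15-representative setting.
- The logistic models are not probability-calibrated, trees are not
  cost-complexity pruned, and no multiple-testing correction is applied at
  screening — all deliberate omissions from the modelled procedure.
- AUC is reported for the logistic route only; a tree with its multiple
  cut-points does not yield a single ROC, so no AUC is recorded for the
  partitioning or prevalence models.
- No scanner harmonisation (e.g. ComBat) is included; tables are assumed
  acquisition-harmonised upstream.
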