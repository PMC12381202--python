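# Methods

`symptomnet` implements a complete symptom-network analysis pipeline for
two-group survey cohorts — children screened positive for sleep disorders
(SDG) versus not (NSDG) — together with a synthetic cohort generator that
carries its own ground truth, so every stage can be validated against known
structure without access to raw survey data.

## The model

Item responses are modelled as a Gaussian graphical model (GGM): a
multivariate normal whose precision matrix `K` encodes conditional
independence.  Edges are partial correlations

    w_ij = -k_ij / sqrt(k_ii k_jj),

the association between two symptoms controlling for all others.  `K` is
estimated by the graphical lasso — L1-penalized Gaussian maximum
likelihood with the penalty on off-diagonal entries — along a decreasing
penalty path, and the penalty is chosen by the Extended Bayesian
Information Criterion

    EBIC_gamma = -2 l + E log n + 4 E gamma log p,

where `E` is the number of edges and `gamma` (default 0.5) controls the
extra sparsity preference; `gamma = 0` reduces to the BIC.

### EBIC likelihood: support-restricted refit

The likelihood term `l` is evaluated at the *unpenalized* Gaussian MLE
restricted to each candidate edge set, not at the shrunken glasso estimate.
Scoring the shrunken estimate systematically favours denser models: in our
recovery experiments (21 nodes, n = 3000, gamma = 0.5, ordinal items) it
yields edge specificity ≈ 0.885 on average, while the refitted score gives
sensitivity ≈ 0.99 and specificity ≈ 0.99.  The restricted MLE is computed
by the same coordinate-descent kernel with a per-element penalty (zero on
the support, prohibitive off it), and refits are cached per distinct
support along the path.  The *returned* weights are still the penalized
path estimate at the selected penalty, the convention users of regularized
symptom networks expect; among penalties selecting the same graph the
smallest one is reported, so the weights carry the least shrinkage
compatible with the selected structure.

The glasso itself is implemented in-package (numba, Friedman's block
coordinate descent, duality-gap stopping at 1e-4 scaled by p).  A single
21-node path of 100 penalties runs in ~30 ms, which is what makes the
permutation and bootstrap studies below tractable on one CPU; unit tests
cross-check the estimates against scikit-learn's `graphical_lasso`.

### Penalty grid

100 log-spaced values from `lambda_max = max |off-diagonal S|` (the empty
model) down to `0.01 lambda_max`, warm-starting each fit from the previous
solution.  Resampling-heavy routines (permutation comparison, bootstraps)
accept a coarser grid through `EstimatorConfig(nlambda=...)`; the
permutation test's validity does not depend on the grid, only on applying
the identical procedure to every permutation.

## Node-level indices

* strength centrality `SC_i = sum_j |w_ij|`;
* expected influence `EI_i = sum_j w_ij` (one-step, signed);
* bridge expected influence `BEI_i`: the signed sum over neighbours in
  *other* communities, with communities fixed a priori by scale membership
  (depression / anxiety / stress / parental);
* predictability: R² of an OLS regression of each node on its selected
  neighbours (nodes with no edges get 0).  OLS on the selected
  neighbourhood is used rather than a separate nodewise-regularized model
  because variance-explained is the quantity of interest and OLS makes it
  directly testable against designs with known R².

Identities that hold by construction and are asserted in tests:
`EI <= SC` elementwise with equality exactly when all incident edges are
nonnegative, and `sum_i EI_i = 2 sum_{i<j} w_ij`.

## Resampling

* **Edge accuracy**: nonparametric bootstrap (children resampled with
  replacement, full re-estimation), percentile 95% CIs; the edge-difference
  test checks whether the bootstrap CI of `w_a - w_b` excludes zero.
* **Stability**: case-dropping bootstrap.  For each drop proportion in
  {0.05, ..., 0.75} the network is re-estimated on subsamples and each
  centrality index is correlated with its full-sample value.  The
  CS-coefficient is the largest proportion whose 5th-percentile correlation
  stays >= 0.7, requiring all smaller proportions to qualify too (>= 0.25
  adequate, >= 0.5 good).  `n_boot` counts resamples per proportion.
  Correlations that are undefined because a centrality vector is constant
  (e.g. an entirely empty network) count as 0, which is why pure-noise data
  yields CS = 0.
* **Comparison (NCT)**: permutation test pooling the children and
  re-estimating both networks per permutation.  Statistics: structure
  `M = max |w^A - w^B|`, global strength `S_diff = |sum|w^A| - sum|w^B||`,
  per-edge differences and per-node strength differences (both
  Holm-corrected).  p-values use the +1 correction,
  `p = (1 + #{perm >= obs}) / (1 + n_perm)`, so they are never zero and the
  test is exact-level.  Note a finite permutation count floors the raw
  p-value at `1/(n_perm+1)`; with 200 permutations no single edge can stay
  Holm-significant across 210 comparisons — family-wise edge claims need
  the full 1000+ permutations.

## Propensity-score matching

Multivariable logistic regression of group on age, gender, region, school
stage and only-child status (statsmodels MLE); greedy 1:1 nearest-neighbor
matching without replacement, caliper 0.01 on the probability scale,
treated units visited in seeded random order, ties to the lowest control
index.  Balance is reported as standardized mean differences (< 0.1 =
balanced) alongside Yates-corrected 2x2 chi-square tests, uncorrected
r x c chi-square tests, and two-sample z tests — the Yates correction
reproduces the published before-matching 2x2 statistics to all printed
digits.

## Screening and scoring

Records are invalid when they fail the trap question, answered in under
10 minutes, straight-lined the full 21-item DASS block, miss more than 20%
of items, or duplicate an earlier row.  Straight-lining is operationalized
as a constant response across an entire instrument; a child who honestly
answers 0 on all 21 items is indistinguishable from a careless one under
this rule, which slightly over-excludes healthy respondents (empirically
< 0.1% of generated cohorts).  Winsorization replaces |z| > 3 entries by
the 1st/99th percentile of the original vector.  Imputation is
chained-equation (linear regression with a Gaussian residual draw for
numeric columns, logistic with a Bernoulli draw for binary), 20 cycles, m
seeded copies; downstream estimation uses the first completed dataset by
default.  Cut-offs: DASS depression > 9 / anxiety > 7 / stress > 4, PSQI
global > 5, SWLS 20 neutral (single-point neutral band by default,
configurable).  Item redundancy uses the goldbricker rule: pairs
correlated >= 0.50 are redundant iff fewer than 25% of
dependent-correlation comparisons (Hittner back-transformed-average z,
alpha = 0.05 per comparison) differ significantly.

## The synthetic cohort generator

The generator defines the study conditions; it is the ground truth every
recovery test measures against.

* **Latent structure.** Ordinal items arise from a latent multivariate
  normal whose precision is `K = I - P` for a sparse partial-correlation
  matrix `P` (unit conditional precisions fix the otherwise
  scale-unidentified map).  DASS items are cut at thresholds giving
  marginal frequencies ≈ (0.50, 0.25, 0.15, 0.10); parental subscale
  totals (0-21) are an affine transform of the latent score.
* **Truths.** Both groups share a within-scale scaffold (weights 0.12-0.33,
  typical of reported regularized symptom networks) with A5 as the bridge
  hub; group-contrasted anchor edges take the published values (D6-D7
  0.52/0.41, A6-A2 0.33/0.29, A6-A7 0.27/0.25, A4-S4 0.20/0.09, S4-S3
  0.20/0.06, A5-D4 0.21/0.25), and the five child-parental edges (A6-PD
  -0.19, A6-PA 0.11, A6-PS 0.15, A5-PA 0.11, D4-PS 0.10) exist only in the
  SDG truth.
* **Confounding.** Demographics follow the surveyed marginals (68% primary
  school, ages ~9.9/14.0 by stage, 49% girls, region .385/.294/.321, 11.7%
  only children); group membership is logistic in the demographics with
  coefficients giving ~12% prevalence and strong school-stage/age
  confounding — the imbalance matching must remove.  PSQI components are
  drawn per group and nudged so the global-score rule (> 5) agrees with
  the group label; sleep duration is N(7.43, 2.14) / N(8.80, 1.54) hours.
* **Invalid records** are injected uniformly at random (trap failure,
  too-fast response, > 20% missing items in equal shares) at rate 0.047,
  matching the published 95.3% validity rate, plus 0.5% benign item-level
  MCAR missingness for the imputation stage to repair.

What the generator does *not* emulate: school/class clustering from the
sampling design, PSQI component dependence, item-level measurement
non-invariance between groups, and informative (MNAR) missingness.
Passing recovery tests therefore show the estimator chain is correct under
a faithful latent-Gaussian ordinal regime, not that real survey data meet
those assumptions.

## Problem sizes and numerical choices

Validation experiments use: recovery at n = 3000 (the published network's
power analysis regime is well inside this), the lambda->0 equivalence at
n = 5000 (tolerance 1e-6 against the direct inverse), type-I error of the
NCT structure test with 100 replicates of 200 permutations at n = 500 per
group on a 10-value penalty grid, CS-coefficients at n = 10,000 with 250
resamples per drop proportion, and matching balance at ~10,000 children.
These sizes keep each experiment's Monte-Carlo error small relative to the
property being asserted while remaining single-CPU-friendly.

Degenerate inputs are handled explicitly: constant vectors (winsorization
warns and returns unchanged; correlation raises naming the column),
non-positive-definite truths (error naming the offending eigenvalue),
subsamples smaller than p+1 (skipped with a warning), fully-missing columns
(error), and empty control pools (error).

## Known limitations

* Pearson correlations on raw 0-3 items attenuate latent associations by
  roughly 10-15%; a polychoric option is out of scope, so recovered edge
  weights underestimate the latent truth even before lasso shrinkage.
* The imputation engine is simplified chained equations (no predictive
  mean matching); adequate here because downstream results are insensitive
  to the imputation engine, but not a replacement for a full MICE analysis.
* The link between case-drop subsets and the between-group centrality
  comparison is implemented as an independent permutation test of per-node
  strength differences; other operationalizations exist.
* No mixed graphical models for categorical nodes, no optimal/full
  matching, no IPTW.
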