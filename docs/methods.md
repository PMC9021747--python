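# Methods

`injuryarch` re-implements a molecular injury-phenotyping pipeline for
kidney transplant indication biopsies: per-biopsy gene-set injury
scores and cross-validated classifier probabilities are combined into a
12-feature matrix, archetypal analysis decomposes that matrix into six
extreme "scenario" phenotypes, and the resulting groups are profiled
clinically and by death-censored graft survival.  Because the original
microarray cohort is external data, the package ships a synthetic
cohort generator that plants the same statistical structure with known
ground truth; every stage is tested against that truth.

## PBT scoring

A pathogenesis-based transcript set (PBT) score is the geometric mean,
over the member probes of a curated set, of the fold change of a biopsy
versus the mean expression of that probe in a control (nephrectomy)
population:

    score(b, S) = exp( (1/|S|) * sum_{p in S} ln( x_{p,b} / mean_{c in controls} x_{p,c} ) )

A score of 1.0 is control-like.  Choices made here:

- The control baseline is the **arithmetic** mean of linear-scale
  control intensities.  A geometric-mean baseline would be a defensible
  alternative; the arithmetic reading of "mean expression" is the
  plainer one and is what the generator calibrates against.
- The geometric mean is computed in log space; this ties exactly with
  the product-root definition and is overflow-safe.
- Probes absent from the matrix are a hard error by default; an
  explicit `drop_missing` flag exists because real arrays lack probes.

The eight canonical PBTs (DAMP, IRRAT, IRITD3, IRITD5, IGT, MCAT, KT1,
KT2) form the first eight columns of the score matrix.

## Classifier probabilities

Four binary clinical endpoints — ci-lesion > 1, ct-lesion > 1,
eGFR <= 30 (boundary included), proteinuria positive — are scored by an
ensemble of probabilistic learners under 10-fold cross-validation.  The
hard contract is leakage hygiene: every sample is scored only by models
fitted on the other nine folds, and the final probability is the
**median across learners**.  The original analysis used twelve learner
implementations that are not enumerated anywhere reproducible; this
package makes the roster configurable and defaults to three diverse
learners (regularised logistic regression, a random forest, and
histogram gradient boosting).  The downstream analysis depends only on
the out-of-fold median contract, which is verified by a permuted-label
test (out-of-fold AUC must stay at chance) and a separable-endpoint
test.  Folds are stratified by label whenever both classes have at
least K members; the fold seed is recorded.

## Archetypal analysis

The n x 12 score table is column-wise z-scored (sample SD) before both
archetypal analysis and PCA.  The source analysis states
standardization only for trend plots; it is applied to the model input
here because the 12 features live on incommensurate scales (fold
changes versus probabilities) and unstandardized PBTs would dominate
both decompositions.  A flag disables it.

AA solves

    min_{A, B} || X - A B X ||_F^2 ,  rows of A and B on the simplex

so archetypes Z = BX are convex combinations of observed biopsies and
every biopsy is a convex mixture of archetypes (scores sum to 1; the
highest score defines the cluster, ties to the lowest index).  The
optimiser alternates:

1. **A-step** — each sample's weights are the exact simplex-constrained
   least-squares projection onto the current archetypes, solved by
   penalty-augmented NNLS (a heavily weighted sum-to-one row appended
   to the design) followed by exact renormalisation.
2. **B-step** — a fast move first: the unconstrained optimal archetypes
   `lstsq(A, X)` are projected row-wise onto conv(X), accepted only if
   the RSS does not increase.  Then one pass of exact block coordinate
   descent over the rows of B: with A and the other rows fixed, the
   optimal row j is the simplex projection of
   `t_j = R_j' a_j / ||a_j||^2` onto conv(X), where `R_j` is the
   residual excluding archetype j.  Each row update is an exact
   minimisation, so the RSS trajectory is monotone — something the
   projection-only step alone does not guarantee (and on tiny instances
   the projection-only scheme demonstrably stalls above the global
   optimum).

Initialisation is furthest-sum vertex seeding for the first restart and
random vertex sets for the remaining restarts (furthest-sum is
deterministic, so restarts would otherwise collapse at small n); the
best of `restarts` runs by RSS is returned (default 10).  Convergence
is a relative RSS change below `tol` (default 1e-6, `max_iter` 500).
k = 6 is the canonical default; an RSS scree utility covers k = 2..7.

Fitted archetypes are labelled by one-to-one (Hungarian) matching of
their natural-scale profiles to built-in reference scenario profiles
(no injury, minor injury, AKI1, AKI2, CKD, CKD/AKI) by Pearson
correlation.  The published label assignment was expert judgment; the
profile-matching rule is a reproducible surrogate.

## PCA co-embedding

The same standardized matrix feeds a full PCA used for visualisation.
Component signs are pinned by feature anchors so refits are
bit-reproducible: PC1 has a positive IRRAT loading (PC1 grows with
injury), PC2 a negative IRRAT loading (AKI sits at negative PC2), PC3 a
negative IGT loading (inflamed injury at negative PC3).  The anchors
are an inference from the reported per-group PC means, recorded in the
model as a convention.  Remaining components orient their
largest-magnitude loading positive.  A Spearman utility ranks probes by
correlation with any PC score (ties break by probe id).

## Cohort analyses

- Biopsies with an estimated cortex fraction below 10% are removed
  (missing estimates retained, logged).
- Histologically unremarkable biopsies ("no major abnormalities") are
  relabelled "clinical AKI" at <= 42 days post-transplant (boundary
  included) and "normal" later.
- Moving averages sort jointly by the ordering variable (stable sort,
  ties keep input order) and slide a 400-biopsy window one biopsy at a
  time; trend plots z-score each archetype score across the cohort
  first, so the y-axis is in SD units and each series is centred at 0.
- Two-group comparisons: Welch's t wherever a t-test is called for
  (group sizes and variances differ throughout), the Wilcoxon rank-sum
  (Mann-Whitney) form for the non-parametric comparison — the compared
  groups are independent and of unequal size, so a paired signed-rank
  test is not applicable — and Fisher's exact test by hypergeometric
  tail summation (verified against full enumeration).

## Survival

Survival analyses use one uniformly random biopsy per patient
(seeded), truncate at 1,095 days, and treat death with a functioning
graft as censoring (death-censored contract).  Kaplan-Meier estimation
backs onto lifelines and is checked against hand-computed product-limit
values and, without censoring, the empirical survivor function.  The
crude "fraction failed by 3 years" counts failures within the horizon
over failures plus records followed at least to the horizon; records
censored earlier are not evaluable.  The source tables print such
fractions without defining evaluability, so this denominator rule is
this package's documented reconstruction.

Variable importance grows an extremely-randomized-trees classifier
(one random threshold per candidate feature — the analog of
single-random-split-point trees) or a random survival forest
(concordance-scored), then measures permutation importance **on an
internal held-out third of the data**.  A fully grown ensemble
memorizes its training set, which makes even pure-noise features look
informative if importance is evaluated in-sample; the held-out
evaluation restores the null calibration (permuted outcomes give
importances statistically indistinguishable from zero).  The canonical
tree count is 10,000; tests use a few hundred.

## Synthetic cohort generator

The generator emulates the study conditions, not real microarrays:

- **Scores** — per biopsy, mixture weights A ~ Dirichlet(0.3·1_6)
  (vertex-heavy but mixed, mirroring "most likely cluster" semantics);
  raw features are A·Z plus Gaussian noise with SD `noise_sd` (default
  0.1) **in units of each feature's mixture SD**, i.e. on the z-score
  scale the analysis standardizes to.  Classifier columns are clipped
  to [0, 1], PBT columns floored at 0.05.  The six 12-feature archetype
  profiles use the published group means for IRRAT, IRITD3, IRITD5,
  IGT, MCAT and KT1; DAMP, KT2 and the four probabilities carry
  documented defaults consistent with scenario semantics.
- **Expression** — 20 probes per PBT set plus null background probes;
  log-normal control baselines, four control samples with mean-one
  noise, and biopsy intensities equal to baseline x target score x
  median-one log-normal probe noise (log-mean 0, so the geometric-mean
  score is unbiased; mean-one multipliers would bias it by
  exp(-sigma^2/2)).
- **Clinical covariates** — conditional on the true cluster: log-normal
  biopsy timing with medians (40, 51, 1070, 867, 2102, 365) days for
  (AKI1, AKI2, minor, CKD/AKI, CKD, no injury); normal eGFR with means
  (22, 27, 52, 32, 35, 53); deceased-donor Bernoulli (0.89, 0.65, 0.67,
  0.73, 0.73, 0.60); rejection categories multinomial with the
  published per-group proportions; lesion scores binomial(3, mean/3).
  Dispersions are not published anywhere; they are documented defaults
  (e.g. log-SD 1.2 for timing, SD 12 for eGFR), calibration knobs
  rather than claims.
- **Survival** — exponential failure times calibrated so
  P(fail <= 1095 d) equals the per-cluster 3-year probabilities
  (defaults 0.26, 0.08, 0.10, 0.30, 0.25, 0.07), uniform administrative
  censoring on [180, 2190] days, and deaths with function injected at
  rate 0.05 as an independent uniform competing time.

Identical seeds give bit-identical cohorts; each stage draws from its
own deterministic stream.  What passing tests show: the pipeline
recovers planted convex-geometry structure, calibrated hazards, and
conditional covariate distributions.  What they do not show: behaviour
under real microarray artefacts (batch effects, probe-level biases,
within-patient longitudinal correlation), none of which the generator
attempts to model.

## Numerical notes and problem sizes

- Simplex-constrained least squares uses NNLS with a penalty row of
  weight 200 x the data magnitude, then renormalises; it matches an
  0.01-step simplex grid oracle to 1e-10 and, inside the full
  optimiser, exhaustive 0.05-step grid search over compositions on
  tiny instances.
- Recovery tests run at n = 1000 with 10 restarts (seconds to a couple
  of minutes); KM calibration at 20,000 records per cluster;
  leakage tests at n = 2000 with the three-learner roster; importance
  calibration with 500 trees and 20 reseeds.  The pipeline CLI default
  is a 600-biopsy cohort.
- Degenerate inputs: constant feature columns standardize to zeros with
  a warning; an archetype with no assigned weight keeps its composition
  row; empty groups report missing statistics; degenerate 2x2 margins
  return p = 1 with a warning.

## Known limitations

- The learner roster and feature set of the original twelve classifiers
  are not reproduced, only their out-of-fold median contract.
- Archetype labels come from profile matching, not expert review.
- The synthetic cohort is a convex-geometry emulation; none of its
  dispersion parameters are estimates of the real cohort.
- Cox models, competing-risks estimators, and clinically augmented risk
  prediction are out of scope.
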