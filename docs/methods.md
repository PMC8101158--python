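# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `symptomnet`, in the order the pipeline runs them.

## Synthetic cohorts (the study conditions)

The generator emulates a pooled primary-care depression-trial cohort at
study entry: ordinal symptom items whose dependence structure is a Gaussian
graphical model with three symptom communities (anxiety, depressive-
cognitive, depressive-physical) and a handful of bridge edges between them.

**Precision construction.** Given a planted partial-correlation matrix P
(zero diagonal), the precision is K = d·(I − P) with diagonal constant
d > 0. Partial correlations −κᵢⱼ/√(κᵢᵢκⱼⱼ) then reproduce P *exactly* and
are invariant to d; K is positive definite iff the largest eigenvalue of P
is below 1, and specs violating this are rejected with the offending
eigenvalue.

**Defaults.** 20 nodes in three near-equal contiguous communities;
within-community edges planted with partial correlation 0.2 on a random 45%
of within-community pairs; one bridge edge of 0.15 between each pair of
communities (so six designated bridge nodes). The 45% density was chosen so
that the entire perturbation family used by the group-comparison studies —
scaling all edges up to 1.5× — still yields a positive-definite model
(eig_max(1.5·P) < 1); at 50% it does not. A 30-node variant is available
but the 20-node network is the default study condition.

**Sampling.** Latent multivariate normal with unit variances; two
log-normal duration covariates (standardised) shift all latent means by
`duration_effect` (default 0.1 — present so covariate correction is
exercised, but not dominant). Redundant item pairs copy the source item's
latent value plus N(0, 0.2²) noise, mimicking the near-collinear item pairs
(loss of pleasure/interest; failure/worthlessness) seen in real BDI-II
data. Latents are cut at equiprobable standard-normal thresholds into 4
levels (depression-like items) or 5 levels (anxiety-like items). The
outcome is items·β + N(0, 1) with a sparse β (three items at 0.5 by
default). A remitter/persister label thresholds a follow-up sum-score
analogue (baseline total × uniform(0.1, 0.9) recovery factor) at < 10,
giving roughly a quarter to a third remitters.

**What the generator does not emulate:** missing data and attrition (the
pipeline assumes complete baseline data), multi-study heterogeneity
(a study label is carried but all subjects are exchangeable), item-specific
threshold asymmetries (all items are equiprobable unless thresholds are
supplied), and treatment-arm effects. Passing tests therefore demonstrate
correctness of the machinery under a faithful ordinal-GGM world, not
robustness to violations of it.

## Screening and redundancy reduction

Near-zero variance uses the frequency-ratio heuristic (most/second-most
common value > 19 and ≤ 2 distinct values); |skewness| > 2 is a
report-only flag, since the rank-based correlations downstream tolerate
skew. Overlap detection considers every pair with Spearman r ≥ 0.5 and
tests, for each third item k, H₀: cor(i,k) = cor(j,k) with the Hittner
(2003) back-transformed-average-z test for overlapping dependent
correlations at α = 0.05; a pair is a merge candidate when fewer than 25%
of the third-item profiles differ. The analytic test is validated in the
test suite against a permutation oracle that swaps the pair within
subjects. Merging takes the first principal component of the standardised
pair, orients it to correlate positively with the pair mean, and linearly
rescales it to the (wider) original Likert range; values stay continuous —
no rounding. Candidates are merged greedily, strongest correlation first,
each item at most once.

## Network estimation

The Spearman matrix (average-rank ties) of the (merged) items is treated as
the covariance of a Gaussian model. If ties push it marginally outside the
PSD cone (below −1e-8), it is projected to the nearest PSD correlation
matrix and the event logged.

- **Glasso path**: 100 log-spaced penalties from λ_max = max|off-diagonal|
  (empty graph) down to λ_max/100, solved by `sklearn`'s graphical lasso
  (tolerance 1e-5). Non-converged points are dropped with a warning.
- **Unregularized refit**: for each distinct edge set on the path, the
  concentration-graph MLE is computed by cyclic regression updates on the
  covariance (the standard graphical-model MLE algorithm); the fitted
  covariance matches S on the diagonal and every edge to 1e-8 and the
  precision is exactly zero elsewhere. Non-decomposable graphs converge
  iteratively; failure to converge raises with the moment gap.
- **EBIC**: −2ℓ + E·log n + 4γ·E·log p with the Gaussian profile
  log-likelihood on S and γ = 0.5 (the field's default; exposed in
  `GGMConfig`). n is the number of subjects after preprocessing.
- **Stepwise search**: from the best refit, single-edge additions/removals
  accepted while EBIC strictly decreases; among equal moves, removals are
  preferred, then lowest (i, j) — this makes the search fully
  deterministic. A step cap (default 200) returns best-so-far with a flag.

Two cheaper estimators are exposed for bootstrap-heavy work:
`estimator="path"` (best unregularized refit on the path, no stepwise) and
`estimator="glasso"` (the regularized precision at the EBIC-optimal
penalty). Duration covariates are corrected by estimating them as extra
nodes and dropping their rows/columns from the reported network, so item
edges are conditioned on them.

## Communities, centrality, stability

Walktrap runs on absolute weights (random-walk transition probabilities
need non-negativity; signed information is retained for the centrality
indices) with walk length 4, cut at maximum modularity; isolated nodes are
singletons. Bootstrap replicates (case resampling, default B = 1000; B =
100 at desk scale) re-run estimation + walktrap and report the community-
count median, SD and 95% percentile CI, plus per-item stability — the
fraction of replicates in which an item remains co-assigned with its
full-sample community co-members (label-free, so no matching problem).

Centralities: EI is the signed row sum. Bridge EI sums a node's signed
weights to other communities; the normalised variant divides by the number
of outside nodes (the exact normaliser in the literature varies, so both
variants are exposed). PC and PR use absolute weights; PR is the
effective-number-of-edges participation ratio (ℓ1² / ℓ2²). Isolated nodes
get PC = PR = 0 by convention. The PC/PR geometric mean is computed first
and z-scored afterwards (population SD); this ordering is recorded here
because the alternative (z-scoring before the mean) is not equivalent.

Edge accuracy uses case-resampled 2.5/97.5 percentile intervals. The CS
coefficient drops {5%, …, 75%} of cases (B = 250 default), correlates
subsample EI with full-sample EI (Pearson), and reports the largest drop
proportion at which ≥ 95% of correlations reach 0.7 with all smaller
proportions also passing; proportions leaving fewer than 3p subjects are
skipped. Shortest paths use Dijkstra with distance 1/|w|.

## Network comparison test

Statistics: global strength S = Σ_{i<j}|wᵢⱼ| per group and |S₁ − S₂|;
structure = max |edge difference|; per-edge |differences|; per-node EI or
strength differences. Group labels are permuted with group sizes preserved
(unequal sizes supported); p = (1 + #{perm ≥ obs}) / (1 + iterations), so
the p floor is 1/(1+iterations) and zero p-values cannot occur. Edge-level
Holm-adjusted tests are reported only when the omnibus structure test is
significant (gate configurable). Failed permutations are redrawn; more than
10% failures aborts.

The default estimator inside the NCT is the same unregularized EBIC search
as the main analysis. The fast mode (`estimator="glasso"`) selects the
penalty once by EBIC *on the pooled sample* — a permutation-invariant
statistic, so exchangeability under the null is preserved — and holds it
fixed across permutations; per-permutation re-selection is available via
`reselect_lambda=True`. Mann-Whitney item-severity differences between
groups are reported descriptively and never gate the network tests.

## Prognosis models

Elastic net over mixing α ∈ {0.1, …, 1.0} and a 100-point log-spaced λ path
per α (down to 1e-3 of the data-derived λ_max), tuned by mean squared error
over 10 independent 10-fold partitions (partitions are a pure function of
(n, folds, repeats, seed) and are shared with the comparator). Predictors
are standardised inside each training fold; final coefficients are
reported on the original scale, and the selected λ is on the
standardised-predictor scale (stated explicitly because conventions
differ). Out-of-fold RMSE/MAE/R² are computed per repeat and averaged;
held-out R² may be negative and is reported as computed. The comparator is
OLS on the depression total and the anxiety-item total with identical
partitions. Duration covariates enter the item model as predictors.

Shapley values use the permutation-sampling estimator: per repetition, one
feature permutation and one background row per subject; walking through the
permutation replacing background values with the subject's own makes the
prediction increments telescope, so per-repetition efficiency is exact and
the per-subject efficiency identity holds up to background-sampling noise
(SE = sd(f(X))/√reps). 500 repetitions by default; fewer than 10 is
rejected. Both mean |value| and mean signed value are reported, since
conventions for "importance" differ; rankings use mean |value|.

## Validation studies and problem sizes

`symptomnet.experiments` (driven by `analysis/07_simulation_studies.py`,
`scripts/acceptance.py` and `tests/test_acceptance.py`) runs:

- **Network recovery** — default cohort, n = 2000: edge-set F1 and weight
  correlation against the planted network (full EBIC search).
- **Community recovery** — ARI of walktrap on the true weights; bootstrap
  (B = 100) community-count median on a generated cohort.
- **NCT calibration** — 60 null replicates × 150 permutations at n =
  500/group (type-I error), 30 replicates at n = 1000/group under 1.5×
  edge inflation (power), fast glasso mode. These are desk-scale counts;
  the functions accept larger values (1000 permutations for full scale).
- **Shapley agreement** — 500 MC repetitions vs the closed form
  βⱼ(xⱼ − mean Xⱼ) for a linear model on independent features (3-SE
  criterion per pair), plus the efficiency identity.
- **Item vs sum-score contrast** — 20 generator seeds, n = 2000, reduced
  CV (2 × 5-fold, α ∈ {0.1, 0.5, 1.0}, 25-λ path) for the win rate under a
  single-item outcome and the null contrast under a total-driven outcome.
- **Stability machinery** — CS on a 10×-replicated n = 400 cohort (tested
  drop proportions {0.25, 0.5, 0.75}; replication fixes the empirical
  population, so the CS should reach the maximum tested proportion) and on
  tiny pure-noise cohorts (should be 0); bootstrap edge-CI coverage pooled
  over 100 simulations (n = 400, 10 nodes, B = 40, unregularized path
  estimator — intervals around lasso-shrunk weights would be biased low by
  construction).

## Known limitations

- Ordinal items attenuate associations: the Spearman matrix of 4-level
  items understates the latent correlations, so estimated edge weights run
  ~10–15% below the planted values (rank ordering is preserved; weight
  *correlations* with truth are ≈ 0.98). Per-edge CIs consequently cover
  planted nonzero weights at slightly below nominal rate (~90% at n = 400)
  while pooled coverage over all pairs is ~98%. No polychoric or
  rank-to-Pearson back-transformation is applied, matching the rank-based
  estimation convention.
- The stepwise EBIC search is greedy and, while deterministic, is not
  guaranteed to find the global EBIC optimum.
- Fused-graphical-lasso joint estimation across studies, IRT-based outcome
  harmonisation, mixed/directed graphical models and >2-group comparisons
  are out of scope.
- The walktrap cut maximises modularity; alternative community methods
  (spinglass, leiden, exploratory graph analysis) are not provided.
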