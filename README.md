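# symptomnet

Symptom-level network analysis and item-level prognosis modelling for
depression/anxiety treatment cohorts.

Clinical trials of depression treatments usually summarise patients by a
sum score (e.g. a BDI-II total), which hides which symptoms matter and how
they interact. `symptomnet` implements, as a tested Python pipeline, the
item-level alternative used in modern psychometric network studies of
primary-care depression cohorts with comorbid anxiety:

- **Item screening and redundancy reduction** — near-zero-variance and skew
  flags; detection of topologically overlapping item pairs (pairs with
  Spearman *r* ≥ 0.5 whose correlation profiles differ significantly for
  fewer than 25% of the remaining items, via the Hittner back-transformed-z
  test for dependent correlations), merged by PCA and rescaled to the
  original Likert range.
- **Gaussian graphical model (GGM) estimation** — edges are partial
  correlations ρᵢⱼ = −κᵢⱼ/√(κᵢᵢκⱼⱼ). A graphical-lasso path (100 penalties)
  proposes edge sets; each is re-fitted *without* regularisation as a
  concentration-graph MLE and scored by the Extended Bayesian Information
  Criterion, EBIC = −2ℓ + E·log n + 4γ·E·log p (γ = 0.5); a greedy stepwise
  search then adds/removes single edges while the EBIC improves. Duration
  covariates can be conditioned on by estimating them as extra nodes.
- **Community, centrality and stability analysis** — bootstrapped walktrap
  communities; expected influence EIᵢ = Σⱼ wᵢⱼ; normalised bridge expected
  influence; participation coefficient PCᵢ = 1 − Σ_c(κᵢ_c/sᵢ)² and
  participation ratio PRᵢ = sᵢ²/Σⱼwᵢⱼ² with their geometric mean; per-edge
  bootstrap CIs and the case-dropping correlation-stability (CS) coefficient.
- **Network comparison test (NCT)** — permutation test (group sizes
  preserved) of global strength S = Σ|wᵢⱼ|, structure (max edge difference),
  individual edges (Holm-gated) and per-node centrality between two groups,
  e.g. future remitters vs. persisters.
- **Prognosis modelling** — elastic-net regression on item severities with
  repeated 10×10-fold cross-validation over an (α, λ) grid vs. OLS on the
  scale totals with *identical* partitions, compared by out-of-fold
  RMSE/MAE/R²; item importance by Monte-Carlo (permutation-sampling)
  Shapley values, which stay meaningful for correlated predictors.
- **Synthetic cohorts with planted truth** — ordinal (Likert) cohorts drawn
  from a known community-structured GGM with designated bridge edges,
  redundant item pairs, duration covariates and a sparse item-driven
  outcome, so every stage above can be validated against ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
cohort (20 items, three communities, n = 2000):

```bash
python analysis/01_simulate_cohort.py --seed 0
python analysis/02_preprocess.py
python analysis/03_estimate_network.py
```

which prints (output from the scripts as run):

```
cohort: 2000 subjects x 20 items
communities (true): [7, 7, 6]
redundant pairs planted: [(0, 3), (7, 9)]
  merged item00 + item03 (r = 0.94, 6% of profiles differ)
  merged item07 + item09 (r = 0.94, 11% of profiles differ)
items after reduction: 18
estimator: unregularized-search (gamma = 0.5), 23 edges on 18 nodes
recovery on 16 unmerged nodes: edge-set F1 = 1.000, weight correlation = 0.982
```

Both planted redundant pairs are detected and merged; the EBIC search
recovers every planted edge with no false positives, and the estimated
partial correlations track the planted weights (r = 0.98; they are slightly
attenuated because ordinal items carry less information than the latent
variables). `04_network_analysis.py` then finds the three planted
communities (bootstrap median 3), `05_compare_groups.py` runs the NCT on
the remitter/persister split (a null result, as both groups share one
planted network), and `06_prognosis.py` shows the item-level elastic net
explaining far more outcome variance than the sum-score model when the
outcome is driven by individual items (R² 0.54 vs 0.13), with the three
predictive items ranked top by Shapley importance.

The same machinery runs on real data: provide a cohort CSV (one row per
subject; item columns, two duration covariates, an `outcome` column,
optional `group`) plus a JSON sidecar with item ranges — see
`symptomnet.io.read_cohort` — or drive everything through
`symptomnet.pipeline.run_pipeline`.

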