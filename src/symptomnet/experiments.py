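"""Self-contained simulation studies exercising the whole pipeline.

Each function plants a known truth with the synthetic module, runs the
corresponding analysis stage, and measures recovery/calibration.  They are
the package's evidence that the machinery works under the study conditions
(three-community ordinal cohorts, within-community partial correlations of
0.2, bridge edges of 0.15); the numbered analysis scripts and the acceptance
runner both call them.  Default rep/permutation counts are desk-scale;
callers can raise them.
"""
from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import adjusted_rand_score

from ._utils import child_seed
from .ggm import GGMConfig, GGMNetwork, estimate_network, ggm_model_select
from .netanalysis import (bootstrap_communities, centrality_stability,
                          edge_accuracy_bootstrap, walktrap_communities)
from .nct import nct_test
from .preprocess import spearman_matrix
from .prognosis import ENRConfig, FittedModel, compare_models, prognosis_analysis, shapley_importance
from .synthetic import (SymptomCohort, default_cohort, default_network,
                        generate_cohort, generate_two_groups, planted_weights)


def edge_set_f1(est: np.ndarray, truth: np.ndarray) -> float:
    """F1 of the estimated edge set against the planted one."""
    iu = np.triu_indices(est.shape[0], 1)
    e, t = est[iu] != 0, truth[iu] != 0
    tp = int((e & t).sum())
    fp = int((e & ~t).sum())
    fn = int((~e & t).sum())
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0


def ggm_recovery(seed: int = 0, n_subjects: int = 2000, n_nodes: int = 20) -> dict:
    """Edge-set F1 and weight correlation of the full EBIC search against the
    planted 3-community network."""
    spec = default_network(n_nodes=n_nodes)
    P = planted_weights(spec)
    coh = generate_cohort(spec, default_cohort(n_subjects=n_subjects, n_nodes=n_nodes,
                                               seed=child_seed(seed, "ggm-recovery")))
    S = spearman_matrix(coh.items, coh.item_names)
    net = ggm_model_select(S, coh.n_subjects, GGMConfig(), nodes=coh.item_names)
    iu = np.triu_indices(n_nodes, 1)
    corr = float(np.corrcoef(net.weights[iu], P[iu])[0, 1])
    return {"f1": edge_set_f1(net.weights, P), "weight_correlation": corr,
            "n": n_subjects, "n_edges_true": int((P[iu] != 0).sum()),
            "n_edges_est": int((net.weights[iu] != 0).sum())}


def community_recovery(seed: int = 0, n_subjects: int = 2000, B: int = 100) -> dict:
    """Walktrap on the true weights (ARI vs planted labels) and bootstrapped
    walktrap on a generated cohort (community-count distribution)."""
    spec = default_network()
    P = planted_weights(spec)
    truth_net = GGMNetwork(nodes=[f"item{k:02d}" for k in range(spec.n_nodes)],
                           weights=P, n=0, estimator="truth", gamma=0.5)
    ari = float(adjusted_rand_score(spec.community_labels,
                                    walktrap_communities(truth_net)))
    coh = generate_cohort(spec, default_cohort(n_subjects=n_subjects,
                                               seed=child_seed(seed, "community")))
    part = bootstrap_communities(coh, GGMConfig(estimator="glasso", n_lambda=20),
                                 B=B, seed=child_seed(seed, "community-boot"))
    return {"ari_true_matrix": ari, "count_median": part.count_median,
            "count_sd": part.count_sd, "count_ci": list(part.count_ci),
            "n": n_subjects, "B": B}


def nct_null_calibration(seed: int = 0, n_reps: int = 60, iterations: int = 150,
                         n_per_group: int = 500, alpha: float = 0.05) -> dict:
    """Type-I error of the global-strength permutation test under the null
    (identical group networks, group_delta = 0)."""
    spec = default_network()
    cfg = GGMConfig(estimator="glasso", n_lambda=12)
    pvals = []
    for rep in range(n_reps):
        cs = dataclasses.replace(
            default_cohort(n_subjects=n_per_group,
                           seed=child_seed(seed, f"nct-null-{rep}")),
            group_delta=0.0)
        c1, c2 = generate_two_groups(spec, cs)
        res = nct_test(c1, c2, cfg, iterations=iterations,
                       seed=child_seed(seed, f"nct-null-perm-{rep}"),
                       keep_networks=False)
        pvals.append(res.p_strength)
    pvals = np.asarray(pvals)
    return {"rejection_rate": float((pvals < alpha).mean()),
            "pvals": pvals.tolist(), "n_reps": n_reps,
            "iterations": iterations, "n_per_group": n_per_group}


def nct_power(seed: int = 0, n_reps: int = 30, iterations: int = 150,
              n_per_group: int = 1000, inflation: float = 1.5,
              alpha: float = 0.05) -> dict:
    """Power of the global-strength test when every group-2 edge is scaled
    by ``inflation``."""
    spec = default_network()
    cfg = GGMConfig(estimator="glasso", n_lambda=12)
    hits = 0
    for rep in range(n_reps):
        cs = dataclasses.replace(
            default_cohort(n_subjects=n_per_group,
                           seed=child_seed(seed, f"nct-pow-{rep}")),
            group_delta=inflation - 1.0)
        c1, c2 = generate_two_groups(spec, cs)
        res = nct_test(c1, c2, cfg, iterations=iterations,
                       seed=child_seed(seed, f"nct-pow-perm-{rep}"),
                       keep_networks=False)
        hits += res.p_strength < alpha
    return {"power": hits / n_reps, "n_reps": n_reps,
            "iterations": iterations, "n_per_group": n_per_group}


def shapley_agreement(seed: int = 0, n_subjects: int = 300, n_features: int = 8,
                      mc_reps: int = 500) -> dict:
    """Monte-Carlo Shapley vs the closed form for a linear model on
    independent Gaussian features, and the efficiency identity."""
    rng = np.random.default_rng(child_seed(seed, "shapley"))
    X = rng.normal(size=(n_subjects, n_features))
    beta = rng.normal(size=n_features)
    model = FittedModel(coef=beta, intercept=0.3,
                        feature_names=[f"x{j}" for j in range(n_features)])
    shap = shapley_importance(model, X, mc_reps=mc_reps,
                              seed=child_seed(seed, "shapley-mc"))
    closed = beta[None, :] * (X - X.mean(axis=0)[None, :])
    within = np.abs(shap["values"] - closed) <= 3 * np.maximum(shap["se"], 1e-12)
    f = model.predict(X)
    gap = shap["values"].sum(axis=1) - (f - f.mean())
    se_eff = f.std() / np.sqrt(mc_reps)
    return {"agreement_rate": float(within.mean()),
            "efficiency_rate": float((np.abs(gap) <= 4 * se_eff).mean()),
            "mc_reps": mc_reps, "n": n_subjects}


_FAST_ENR = dict(repeats=2, folds=5, n_lambda=25,
                 alpha_grid=np.array([0.1, 0.5, 1.0]))


def item_vs_sumscore(seed: int = 0, n_seeds: int = 20, n_subjects: int = 2000) -> dict:
    """Out-of-fold R^2 contrast between the item-level elastic net and the
    sum-score OLS under two planted outcome regimes: a single predictive item
    (item model should win) and a uniform total-driven outcome (no gain)."""
    spec = default_network()
    wins = 0
    deltas_single = []
    for s in range(n_seeds):
        coh = generate_cohort(spec, default_cohort(
            n_subjects=n_subjects, seed=child_seed(seed, f"single-{s}"),
            outcome_items={5: 1.0}))
        rep = prognosis_analysis(coh, ENRConfig(seed=child_seed(seed, f"cv-{s}"),
                                                **_FAST_ENR), run_shapley=False)
        d = compare_models(rep)["r2"]["diff"]
        deltas_single.append(d)
        wins += d > 0
    deltas_total = []
    for s in range(max(n_seeds // 2, 3)):
        cs = dataclasses.replace(
            default_cohort(n_subjects=n_subjects, seed=child_seed(seed, f"tot-{s}")),
            outcome_betas=np.full(spec.n_nodes, 0.15))
        coh = generate_cohort(spec, cs)
        rep = prognosis_analysis(coh, ENRConfig(seed=child_seed(seed, f"cvt-{s}"),
                                                **_FAST_ENR), run_shapley=False)
        deltas_total.append(compare_models(rep)["r2"]["diff"])
    return {"item_win_rate": wins / n_seeds,
            "delta_r2_single_item_mean": float(np.mean(deltas_single)),
            "delta_r2_total_driven_mean_abs": float(np.mean(np.abs(deltas_total))),
            "n_seeds": n_seeds, "n": n_subjects}


def _noise_cohort(n: int, p: int, seed: int) -> SymptomCohort:
    rng = np.random.default_rng(seed)
    items = rng.integers(0, 4, size=(n, p)).astype(float)
    return SymptomCohort(items=items, item_names=[f"item{k:02d}" for k in range(p)],
                         item_ranges=[(0, 3)] * p, covariates=np.zeros((n, 2)),
                         outcome=np.zeros(n))


def stability_machinery(seed: int = 0, base_n: int = 400, B_cs: int = 30,
                        n_noise_seeds: int = 5) -> dict:
    """CS coefficient on a 10x-replicated cohort (should hit the maximum
    tested drop proportion) and on tiny pure-noise cohorts (should be 0)."""
    spec = default_network()
    cfg = GGMConfig(estimator="glasso", n_lambda=12)
    base = generate_cohort(spec, default_cohort(n_subjects=base_n,
                                                seed=child_seed(seed, "cs-base")))
    tiled = base.subset(np.tile(np.arange(base_n), 10))
    props = np.array([0.25, 0.5, 0.75])
    rep = centrality_stability(tiled, cfg, drop_proportions=props, B=B_cs,
                               seed=child_seed(seed, "cs-tiled"))
    cs_noise = []
    for s in range(n_noise_seeds):
        noise = _noise_cohort(100, 10, child_seed(seed, f"cs-noise-{s}"))
        r = centrality_stability(noise, cfg, drop_proportions=np.array([0.1, 0.25]),
                                 B=B_cs, seed=child_seed(seed, f"cs-noise-b-{s}"))
        cs_noise.append(r.cs_coefficient)
    return {"cs_replicated": rep.cs_coefficient, "cs_max_tested": float(props.max()),
            "cs_noise": cs_noise,
            "cs_noise_zero_fraction": float(np.mean(np.asarray(cs_noise) == 0.0))}


def edge_ci_coverage(seed: int = 0, n_sims: int = 100, B: int = 40,
                     n_subjects: int = 400, n_nodes: int = 10) -> dict:
    """Coverage of bootstrap percentile edge CIs against the planted weights,
    pooled over node pairs and simulation repetitions.

    Uses the unregularized path estimator: percentile intervals around the
    lasso-shrunk weights would be biased low and systematically miss the
    planted values.
    """
    spec = default_network(n_nodes=n_nodes)
    P = planted_weights(spec)
    iu = np.triu_indices(n_nodes, 1)
    truth = P[iu]
    cfg = GGMConfig(estimator="path", n_lambda=12)
    covered = np.zeros(len(truth))
    for s in range(n_sims):
        coh = generate_cohort(spec, default_cohort(
            n_subjects=n_subjects, n_nodes=n_nodes,
            seed=child_seed(seed, f"cov-{s}")))
        rep = edge_accuracy_bootstrap(coh, cfg, B=B,
                                      seed=child_seed(seed, f"cov-b-{s}"))
        covered += (rep.edge_ci_lower <= truth) & (truth <= rep.edge_ci_upper)
    rate = covered / n_sims
    nz = truth != 0
    return {"coverage_all": float(rate.mean()),
            "coverage_true_edges": float(rate[nz].mean()),
            "coverage_null_edges": float(rate[~nz].mean()),
            "n_sims": n_sims, "B": B, "n": n_subjects}
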