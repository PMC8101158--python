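import numpy as np
import pytest
from scipy import stats

import symptomnet as sn
from oracles import partial_corr_by_regression
from symptomnet.synthetic import (CohortSpec, NetworkSpec, _discretize,
                                  build_precision_matrix, equiprobable_thresholds,
                                  generate_cohort, generate_two_groups,
                                  latent_correlation, perturb_network, planted_weights)


def _spec(n, labels, **kw):
    return NetworkSpec(n_nodes=n, community_labels=np.asarray(labels), **kw)


class TestPrecisionMatrix:
    def test_no_edges_gives_independence(self):
        spec = _spec(4, [1, 1, 2, 2], within_density=0.0)
        _, rho = build_precision_matrix(spec)
        assert np.allclose(rho, 0.0)

    def test_two_nodes_single_edge(self):
        spec = _spec(2, [1, 2], bridge_edges=[(0, 1, 0.3)], within_density=0.0)
        _, rho = build_precision_matrix(spec)
        assert rho[0, 1] == pytest.approx(0.3, abs=1e-12)

    def test_planted_weights_reproduced_from_inverted_precision(self, planted_spec):
        """Invert K, then recover each within-community partial correlation by
        the conditional-covariance definition: must equal within_weight."""
        K, rho = build_precision_matrix(planted_spec)
        sigma = np.linalg.inv(K)
        P = planted_weights(planted_spec)
        planted = np.argwhere(np.triu(P, 1) != 0)
        assert len(planted) > 10
        for i, j in planted[:12]:
            oracle = partial_corr_by_regression(sigma, int(i), int(j))
            assert oracle == pytest.approx(P[i, j], abs=1e-6)
        assert np.allclose(rho, P, atol=1e-12)

    def test_partial_correlations_invariant_to_diagonal_scale(self, planted_spec):
        import dataclasses
        scaled = dataclasses.replace(planted_spec, base_diagonal=3.7)
        _, rho1 = build_precision_matrix(planted_spec)
        _, rho2 = build_precision_matrix(scaled)
        assert np.allclose(rho1, rho2)

    def test_non_positive_definite_rejected_with_eigenvalue(self):
        spec = _spec(3, [1, 2, 3],
                     bridge_edges=[(0, 1, 0.9), (1, 2, 0.9), (0, 2, 0.9)])
        with pytest.raises(ValueError, match="eigenvalue"):
            build_precision_matrix(spec)

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            _spec(3, [1, 1, 2], bridge_edges=[(1, 1, 0.2)])


class TestGenerateCohort:
    def test_empty_cohort_has_valid_metadata(self, planted_spec):
        coh = generate_cohort(planted_spec, CohortSpec(n_subjects=0))
        assert coh.n_subjects == 0
        assert len(coh.item_names) == planted_spec.n_nodes
        assert coh.item_ranges[0] == (0, 3)

    def test_seed_determinism(self, planted_spec):
        spec = sn.default_cohort(n_subjects=200, seed=5)
        a = generate_cohort(planted_spec, spec)
        b = generate_cohort(planted_spec, spec)
        assert np.array_equal(a.items, b.items)
        assert np.array_equal(a.outcome, b.outcome)
        assert np.array_equal(a.covariates, b.covariates)

    def test_zero_betas_decouple_outcome(self, planted_spec):
        spec = CohortSpec(n_subjects=4000, outcome_betas=np.zeros(20), seed=3)
        coh = generate_cohort(planted_spec, spec)
        r = np.corrcoef(coh.items.sum(axis=1), coh.outcome)[0, 1]
        assert abs(r) < 0.05

    def test_values_within_declared_ranges(self, cohort2000):
        cohort2000.validate()
        for k, (lo, hi) in enumerate(cohort2000.item_ranges):
            assert cohort2000.items[:, k].min() >= lo
            assert cohort2000.items[:, k].max() <= hi

    def test_discretization_monotone(self):
        cuts = equiprobable_thresholds(4)
        x = np.sort(np.random.default_rng(0).normal(size=200))[:, None]
        cats = _discretize(x, [cuts])[:, 0]
        assert (np.diff(cats) >= 0).all()

    def test_redundant_pair_has_highest_spearman(self, planted_spec):
        spec = sn.default_cohort(n_subjects=1500, seed=9, redundant_pairs=[(3, 4)])
        coh = generate_cohort(planted_spec, spec)
        R = stats.spearmanr(coh.items).statistic
        np.fill_diagonal(R, 0)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        assert {i, j} == {3, 4}

    def test_observed_spearman_tracks_latent_model(self, planted_spec, cohort2000):
        """Spearman correlations of the discretized items should correlate
        strongly with the model-implied latent correlations (the implied
        marginal correlation is a monotone attenuation of the latent one)."""
        implied = latent_correlation(planted_spec)
        obs = stats.spearmanr(cohort2000.items).statistic
        iu = np.triu_indices(planted_spec.n_nodes, 1)
        assert np.corrcoef(obs[iu], implied[iu])[0, 1] > 0.9

    def test_implied_marginal_by_numerical_integration(self, planted_spec):
        """For a few pairs, compute the implied Pearson correlation of the
        discretized items by integrating the bivariate normal over the
        threshold grid, and compare with a large generated sample."""
        from scipy.stats import multivariate_normal

        implied = latent_correlation(planted_spec)
        cuts = equiprobable_thresholds(4)
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        big = generate_cohort(planted_spec, sn.default_cohort(n_subjects=40000, seed=21))

        def implied_pearson(r):
            mvn = multivariate_normal(mean=[0, 0], cov=[[1, r], [r, 1]])
            probs = np.zeros((4, 4))
            cdf = np.zeros((5, 5))
            for a in range(5):
                for b in range(5):
                    if np.isinf(edges[a]) and edges[a] < 0 or np.isinf(edges[b]) and edges[b] < 0:
                        cdf[a, b] = 0.0
                    else:
                        cdf[a, b] = mvn.cdf([min(edges[a], 8), min(edges[b], 8)])
            for a in range(4):
                for b in range(4):
                    probs[a, b] = cdf[a + 1, b + 1] - cdf[a, b + 1] - cdf[a + 1, b] + cdf[a, b]
            vals = np.arange(4)
            pa, pb = probs.sum(1), probs.sum(0)
            mu_a, mu_b = vals @ pa, vals @ pb
            cov = (np.outer(vals - mu_a, vals - mu_b) * probs).sum()
            return cov / np.sqrt(((vals - mu_a) ** 2 @ pa) * ((vals - mu_b) ** 2 @ pb))

        pairs = [(0, 1), (0, 2), (1, 3)]
        for i, j in pairs:
            want = implied_pearson(implied[i, j])
            got = np.corrcoef(big.items[:, i], big.items[:, j])[0, 1]
            assert got == pytest.approx(want, abs=0.03)

    def test_duration_effect_shifts_item_means(self, planted_spec):
        spec = CohortSpec(n_subjects=5000, duration_effect=0.5, seed=4)
        coh = generate_cohort(planted_spec, spec)
        dz = coh.covariates.sum(axis=1)
        hi = coh.items[dz > np.median(dz)].mean()
        lo = coh.items[dz <= np.median(dz)].mean()
        assert hi > lo


class TestTwoGroups:
    def test_null_delta_preserves_true_network(self, planted_spec):
        P = planted_weights(planted_spec)
        assert np.allclose(perturb_network(planted_spec, 0.0), P)

    def test_scalar_delta_scales_global_strength(self, planted_spec):
        P = planted_weights(planted_spec)
        P2 = perturb_network(planted_spec, 0.5)
        assert np.abs(P2).sum() == pytest.approx(1.5 * np.abs(P).sum())

    def test_single_edge_delta_leaves_others_identical(self, planted_spec):
        P = planted_weights(planted_spec)
        i, j, w = planted_spec.bridge_edges[0]
        delta = np.zeros_like(P)
        delta[i, j] = delta[j, i] = 0.05
        P2 = perturb_network(planted_spec, delta)
        assert P2[i, j] == pytest.approx(w + 0.05)
        mask = np.ones_like(P, dtype=bool)
        mask[i, j] = mask[j, i] = False
        assert np.array_equal(P2[mask], P[mask])

    def test_groups_generated_and_labelled(self, planted_spec):
        import dataclasses
        cs = dataclasses.replace(sn.default_cohort(n_subjects=100, seed=1), group_delta=0.0)
        c1, c2 = generate_two_groups(planted_spec, cs)
        assert c1.n_subjects == c2.n_subjects == 100
        assert set(c1.group) == {"group1"} and set(c2.group) == {"group2"}
        assert not np.array_equal(c1.items, c2.items)

    def test_delta_breaking_pd_rejected(self, planted_spec):
        with pytest.raises(ValueError, match="positive definite"):
            perturb_network(planted_spec, 5.0)

    def test_missing_delta_rejected(self, planted_spec):
        with pytest.raises(ValueError, match="group_delta"):
            generate_two_groups(planted_spec, sn.default_cohort(n_subjects=10))
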