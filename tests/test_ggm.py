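import dataclasses

import numpy as np
import pytest

import symptomnet as sn
from oracles import glasso_objective_minimize
from symptomnet._utils import partial_correlations
from symptomnet.ggm import (GGMConfig, GGMNetwork, ebic, estimate_network,
                            gaussian_loglik, ggm_model_select, glasso_path,
                            refit_unregularized, _adjacency, _n_edges)
from symptomnet.preprocess import spearman_matrix
from symptomnet.synthetic import CohortSpec, generate_cohort, planted_weights


@pytest.fixture(scope="module")
def toy_S():
    rng = np.random.default_rng(0)
    A = rng.normal(size=(400, 4))
    A[:, 1] += 0.6 * A[:, 0]
    A[:, 2] += 0.4 * A[:, 1]
    return np.corrcoef(A, rowvar=False)


class TestGlassoPath:
    def test_largest_penalty_gives_empty_graph(self, toy_S):
        path = glasso_path(toy_S, 400, GGMConfig(n_lambda=5))
        lam0, _, A0 = path[0]
        assert lam0 == pytest.approx(np.abs(toy_S - np.eye(4)).max())
        assert not A0.any()

    def test_two_node_small_penalty_recovers_marginal(self):
        S = np.array([[1.0, 0.45], [0.45, 1.0]])
        path = glasso_path(S, 1000, GGMConfig(n_lambda=30, lambda_min_ratio=1e-4))
        _, K, _ = path[-1]
        rho = partial_correlations(K)
        assert rho[0, 1] == pytest.approx(0.45, abs=1e-3)

    def test_matches_direct_objective_minimizer(self, toy_S):
        """glasso solution vs a proximal-gradient minimizer of the penalized
        likelihood written independently of sklearn."""
        lam = 0.08
        path = glasso_path(toy_S, 400, GGMConfig(n_lambda=2, lambda_min_ratio=lam /
                                                 np.abs(toy_S - np.eye(4)).max(),
                                                 glasso_tol=1e-8))
        K_pkg = path[-1][1]
        K_oracle = glasso_objective_minimize(toy_S, lam)
        assert np.abs(K_pkg - K_oracle).max() < 1e-4

    def test_warns_when_n_below_p(self, toy_S):
        with pytest.warns(UserWarning, match="unstable"):
            glasso_path(toy_S, 3, GGMConfig(n_lambda=3))


class TestRefitUnregularized:
    def test_saturated_graph_inverts_S(self, toy_S):
        A = ~np.eye(4, dtype=bool)
        assert np.allclose(refit_unregularized(toy_S, 400, A), np.linalg.inv(toy_S))

    def test_empty_graph_gives_diagonal(self, toy_S):
        A = np.zeros((4, 4), dtype=bool)
        K = refit_unregularized(toy_S, 400, A)
        assert np.allclose(K, np.diag(1.0 / np.diag(toy_S)))

    def test_chain_moment_constraints(self, toy_S):
        """Defining property of the concentration-graph MLE: fitted covariance
        equals S on the diagonal and on every edge; precision is exactly zero
        off the graph."""
        A = np.zeros((4, 4), dtype=bool)
        for i in range(3):
            A[i, i + 1] = A[i + 1, i] = True
        K = refit_unregularized(toy_S, 400, A)
        sigma = np.linalg.inv(K)
        mask = A | np.eye(4, dtype=bool)
        assert np.abs(sigma - toy_S)[mask].max() < 1e-8
        assert np.abs(K[~mask]).max() == 0.0

    def test_nondecomposable_cycle_converges(self):
        """4-cycle (chordless) is non-decomposable; the iterative fit must
        still satisfy the moment constraints."""
        rng = np.random.default_rng(1)
        A_ = rng.normal(size=(500, 4))
        S = np.corrcoef(A_, rowvar=False)
        A = np.zeros((4, 4), dtype=bool)
        for i, j in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            A[i, j] = A[j, i] = True
        K = refit_unregularized(S, 500, A)
        sigma = np.linalg.inv(K)
        mask = A | np.eye(4, dtype=bool)
        assert np.abs(sigma - S)[mask].max() < 1e-8


class TestEBIC:
    @pytest.mark.parametrize("loglik,E,n,p,gamma,expected", [
        (-50.0, 0, 100, 10, 0.5, 100.0),
        (-100.0, 5, 100, 10, 0.5, 200.0 + 5 * np.log(100) + 10 * np.log(10)),
    ])
    def test_formula(self, loglik, E, n, p, gamma, expected):
        assert ebic(loglik, E, n, p, gamma) == pytest.approx(expected, abs=1e-12)

    def test_gamma_zero_reduces_to_bic(self):
        assert ebic(-80.0, 7, 200, 15, 0.0) == pytest.approx(160.0 + 7 * np.log(200))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            ebic(-1.0, 0, 0, 5, 0.5)


class TestModelSelect:
    def test_independence_data_near_empty_network(self):
        """Under the null, the conservative EBIC search should keep at most
        one spurious edge in at least 9 of 10 seeds."""
        ok = 0
        cfg = GGMConfig(n_lambda=20)
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.integers(0, 4, size=(2000, 10)).astype(float)
            S = spearman_matrix(X)
            net = ggm_model_select(S, 2000, cfg)
            if _n_edges(_adjacency(net.precision)) <= 1:
                ok += 1
        assert ok >= 9

    def test_two_correlated_variables_single_edge(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=3000)
        y = 0.8 * x + 0.6 * rng.normal(size=3000)
        S = spearman_matrix(np.column_stack([x, y]))
        net = ggm_model_select(S, 3000, GGMConfig(n_lambda=20))
        assert net.weights[0, 1] == pytest.approx(S[0, 1], abs=0.01)

    def test_selected_ebic_not_worse_than_path_refits(self, cohort2000):
        cfg = GGMConfig(n_lambda=20)
        S = spearman_matrix(cohort2000.items)
        net = ggm_model_select(S, 2000, cfg)
        for _, _, A in glasso_path(S, 2000, cfg):
            try:
                K = refit_unregularized(S, 2000, A)
            except RuntimeError:
                continue
            score = ebic(gaussian_loglik(S, K, 2000), _n_edges(A), 2000, 20, cfg.gamma)
            assert net.ebic <= score + 1e-9

    def test_partial_correlation_identity(self, cohort2000):
        S = spearman_matrix(cohort2000.items)
        net = ggm_model_select(S, 2000, GGMConfig(n_lambda=15, estimator="path"))
        K = net.precision
        d = np.sqrt(np.diag(K))
        expect = -K / np.outer(d, d)
        np.fill_diagonal(expect, 0.0)
        assert np.allclose(net.weights, expect, atol=1e-12)

    def test_deterministic_given_inputs(self, toy_S):
        cfg = GGMConfig(n_lambda=10)
        a = ggm_model_select(toy_S, 400, cfg)
        b = ggm_model_select(toy_S, 400, cfg)
        assert np.array_equal(a.weights, b.weights)
        assert a.ebic == b.ebic


class TestCovariateCorrection:
    def test_independent_covariates_leave_network_unchanged(self, planted_spec):
        """duration_effect=0: corrected vs uncorrected networks nearly equal
        (the empirical counterpart of a negligible confounding effect)."""
        spec = CohortSpec(n_subjects=2000, duration_effect=0.0, seed=30)
        coh = generate_cohort(planted_spec, spec)
        cfg = GGMConfig(n_lambda=20, estimator="path")
        net_c = estimate_network(coh, cfg, correct_covariates=True)
        net_u = estimate_network(coh, cfg, correct_covariates=False)
        iu = np.triu_indices(planted_spec.n_nodes, 1)
        r = np.corrcoef(net_c.weights[iu], net_u.weights[iu])[0, 1]
        assert r > 0.99
        assert net_c.covariates_corrected == ["dur_depression", "dur_anxiety"]

    def test_common_cause_edge_shrinks_toward_direct_effect(self):
        """A confounder driving two otherwise-unlinked variables inflates
        their marginal partial correlation; conditioning on it shrinks the
        edge toward the planted zero direct effect."""
        rng = np.random.default_rng(31)
        n = 4000
        conf = rng.normal(size=n)
        x = 0.7 * conf + rng.normal(size=n)
        y = 0.7 * conf + rng.normal(size=n)
        others = rng.normal(size=(n, 2))
        items = np.column_stack([x, y, others])
        from symptomnet.synthetic import SymptomCohort
        coh = SymptomCohort(items=items, item_names=["x", "y", "a", "b"],
                            item_ranges=[(-10, 10)] * 4,
                            covariates=np.column_stack([conf, rng.normal(size=n)]),
                            outcome=np.zeros(n))
        cfg = GGMConfig(n_lambda=20, estimator="path")
        net_u = estimate_network(coh, cfg, correct_covariates=False)
        net_c = estimate_network(coh, cfg, correct_covariates=True)
        assert abs(net_c.weights[0, 1]) < abs(net_u.weights[0, 1])
        assert abs(net_c.weights[0, 1]) < 0.05

    def test_constant_covariate_dropped_with_warning(self, cohort400):
        coh = cohort400
        coh2 = dataclasses.replace  # noqa: F841  (kept simple below)
        import copy
        c = copy.deepcopy(coh)
        c.covariates = np.column_stack([c.covariates[:, 0], np.full(c.n_subjects, 3.0)])
        with pytest.warns(UserWarning, match="constant covariate"):
            net = estimate_network(c, GGMConfig(n_lambda=10, estimator="glasso"))
        assert net.covariates_corrected == ["dur_depression"]


class TestGGMNetworkInvariants:
    def test_asymmetric_weights_rejected(self):
        W = np.zeros((3, 3))
        W[0, 1] = 0.2
        with pytest.raises(ValueError, match="symmetric"):
            GGMNetwork(nodes=list("abc"), weights=W, n=10, estimator="t", gamma=0.5)

    def test_nonzero_diagonal_rejected(self):
        W = np.eye(3) * 0.1
        with pytest.raises(ValueError, match="diagonal"):
            GGMNetwork(nodes=list("abc"), weights=W, n=10, estimator="t", gamma=0.5)
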