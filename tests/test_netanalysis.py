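import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import symptomnet as sn
from oracles import (bridge_ei_loop, expected_influence_loop, global_strength_loop,
                     participation_loop, shortest_path_enumerate)
from symptomnet.ggm import GGMConfig, GGMNetwork
from symptomnet.netanalysis import (bootstrap_communities, bridge_expected_influence,
                                    centrality_stability, centrality_table,
                                    edge_accuracy_bootstrap, expected_influence,
                                    participation_metrics, severity_centrality_correlation,
                                    shortest_paths, walktrap_communities)


def _net(W, names=None):
    names = names or [f"n{i}" for i in range(W.shape[0])]
    return GGMNetwork(nodes=names, weights=W, n=0, estimator="fixture", gamma=0.5)


class TestWalktrap:
    def test_two_disconnected_cliques(self):
        W = np.zeros((6, 6))
        for i in range(3):
            for j in range(i + 1, 3):
                W[i, j] = W[j, i] = 0.3
                W[i + 3, j + 3] = W[j + 3, i + 3] = 0.3
        assign = walktrap_communities(_net(W))
        assert len(np.unique(assign)) == 2
        assert len(np.unique(assign[:3])) == 1 and len(np.unique(assign[3:])) == 1

    def test_single_clique_one_community(self):
        W = np.full((5, 5), 0.25)
        np.fill_diagonal(W, 0.0)
        assert len(np.unique(walktrap_communities(_net(W)))) == 1

    def test_planted_three_block_recovered_exactly(self, planted_spec, true_network):
        assign = walktrap_communities(true_network)
        assert adjusted_rand_score(planted_spec.community_labels, assign) == 1.0

    def test_empty_network_all_singletons(self):
        with pytest.warns(UserWarning, match="singleton"):
            assign = walktrap_communities(_net(np.zeros((4, 4))))
        assert len(np.unique(assign)) == 4


class TestCentralityOracles:
    def test_expected_influence_examples(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.3
        W[0, 2] = W[2, 0] = -0.2
        assert np.allclose(expected_influence(_net(W)), [0.1, 0.3, -0.2])
        assert np.allclose(expected_influence(_net(np.zeros((4, 4)))), 0.0)

    def test_oracle_equivalence_small_graphs(self, small_weight_graphs):
        for W, comm in small_weight_graphs:
            net = _net(W)
            assert np.abs(expected_influence(net) - expected_influence_loop(W)).max() < 1e-12
            for norm in (True, False):
                got = bridge_expected_influence(net, comm, normalise=norm)
                assert np.abs(got - bridge_ei_loop(W, comm, norm)).max() < 1e-12
            pc, pr, _ = participation_metrics(net, comm)
            pc_o, pr_o = participation_loop(W, comm)
            assert np.abs(pc - pc_o).max() < 1e-12
            assert np.abs(pr - pr_o).max() < 1e-12

    def test_bridge_ei_within_only_zero(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.4
        comm = np.array([1, 1, 2, 2])
        assert bridge_expected_influence(_net(W), comm, normalise=False)[0] == 0.0

    def test_bridge_ei_single_cross_edge(self):
        W = np.zeros((4, 4))
        W[0, 2] = W[2, 0] = 0.25
        comm = np.array([1, 1, 2, 2])
        bei = bridge_expected_influence(_net(W), comm, normalise=False)
        assert bei[0] == pytest.approx(0.25)

    def test_bridge_ei_sum_identity(self, small_weight_graphs):
        """Unnormalised bridge EI sums to twice the signed cross-community
        weight total."""
        for W, comm in small_weight_graphs:
            if len(np.unique(comm)) < 2:
                continue
            bei = bridge_expected_influence(_net(W), comm, normalise=False)
            cross = sum(W[i, j] for i in range(len(comm)) for j in range(i + 1, len(comm))
                        if comm[i] != comm[j])
            assert bei.sum() == pytest.approx(2 * cross, abs=1e-12)

    def test_participation_examples(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 0.2
        W[0, 2] = W[2, 0] = 0.2
        comm = np.array([1, 1, 2, 2, 2])
        pc, pr, pcpr = participation_metrics(_net(W), comm)
        assert pc[0] == pytest.approx(0.5)  # equal split across 2 communities
        assert pr[0] == pytest.approx(2.0)  # two equal edges
        assert pcpr[0] == pytest.approx(np.sqrt(0.5 * 2.0))
        assert pc[3] == 0.0 and pr[3] == 0.0  # isolated

    def test_ei_linear_in_weights(self, small_weight_graphs):
        W, _ = small_weight_graphs[1]
        assert np.allclose(expected_influence(_net(3.0 * W)),
                           3.0 * expected_influence(_net(W)))

    def test_pc_relabel_invariant_pr_partition_free(self, small_weight_graphs):
        W, comm = small_weight_graphs[2]
        net = _net(W)
        pc1, pr1, _ = participation_metrics(net, comm)
        relabel = np.where(comm == 1, 7, 3)
        pc2, pr2, _ = participation_metrics(net, relabel)
        assert np.allclose(pc1, pc2)
        other = np.ones_like(comm)
        _, pr3, _ = participation_metrics(net, other)
        assert np.allclose(pr1, pr3)


class TestShortestPaths:
    def test_direct_edge_beats_detour(self):
        W = np.zeros((3, 3))
        W[0, 2] = W[2, 0] = 0.5
        W[0, 1] = W[1, 0] = 0.3
        W[1, 2] = W[2, 1] = 0.3
        res = shortest_paths(_net(W, list("abc")), "a", "c")
        assert res.path == ["a", "c"]
        assert res.distance == pytest.approx(2.0)

    def test_chain_path(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.4
        W[1, 2] = W[2, 1] = 0.4
        res = shortest_paths(_net(W, list("abc")), "a", "c")
        assert res.path == ["a", "b", "c"]

    def test_disconnected_pair_reports_no_path(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.4
        res = shortest_paths(_net(W), "n0", "n3")
        assert res.path is None and np.isinf(res.distance)

    def test_matches_enumeration_oracle(self, small_weight_graphs):
        for W, _ in small_weight_graphs:
            names = [f"n{i}" for i in range(W.shape[0])]
            net = _net(W, names)
            oracle_path, oracle_d = shortest_path_enumerate(W, 0, W.shape[0] - 1)
            res = shortest_paths(net, names[0], names[-1])
            if oracle_path is None:
                assert res.path is None
            else:
                assert res.distance == pytest.approx(oracle_d, abs=1e-10)


class TestBootstraps:
    def test_bootstrap_b1_median_is_single_count(self, cohort400, fast_config):
        part = bootstrap_communities(cohort400, fast_config, B=1, seed=0)
        assert part.count_median == part.bootstrap_counts[0]

    def test_bootstrap_reproducible(self, cohort400, fast_config):
        a = bootstrap_communities(cohort400, fast_config, B=5, seed=3)
        b = bootstrap_communities(cohort400, fast_config, B=5, seed=3)
        assert np.array_equal(a.bootstrap_counts, b.bootstrap_counts)
        assert np.allclose(a.item_stability, b.item_stability)

    def test_edge_bootstrap_b2_degenerate_interval(self, cohort400, fast_config):
        rep = edge_accuracy_bootstrap(cohort400, fast_config, B=2, seed=1)
        assert (rep.edge_ci_lower <= rep.edge_ci_upper).all()
        assert rep.n_boot == 2

    def test_strong_edge_ci_excludes_zero(self, cohort2000, planted_spec, fast_config):
        from symptomnet.synthetic import planted_weights
        P = planted_weights(planted_spec)
        rep = edge_accuracy_bootstrap(cohort2000, fast_config, B=40, seed=2)
        iu = np.triu_indices(planted_spec.n_nodes, 1)
        strongest = np.argmax(P[iu])
        assert rep.edge_ci_lower[strongest] > 0

    def test_cs_rejects_bad_proportions(self, cohort400, fast_config):
        with pytest.raises(ValueError):
            centrality_stability(cohort400, fast_config, drop_proportions=[0.0, 0.5])


class TestSeverityCentrality:
    def test_constant_centrality_reported_nan(self, cohort400):
        table = centrality_table(_net(np.zeros((20, 20)),
                                      list(cohort400.item_names)),
                                 np.ones(20, dtype=int))
        out = severity_centrality_correlation(cohort400, table)
        assert np.isnan(out["mean"]["ei"][0])

    def test_planted_proportional_severity(self, cohort2000, fast_config):
        """Construct centrality equal to the item means: r must be ~1."""
        net = sn.estimate_network(cohort2000, fast_config, correct_covariates=False)
        assign = walktrap_communities(net)
        table = centrality_table(net, assign)
        table.ei = cohort2000.items.mean(axis=0).copy()
        out = severity_centrality_correlation(cohort2000, table)
        assert out["mean"]["ei"][0] == pytest.approx(1.0)

    def test_random_permutation_gives_small_r(self, cohort2000, fast_config):
        rng = np.random.default_rng(0)
        net = sn.estimate_network(cohort2000, fast_config, correct_covariates=False)
        assign = walktrap_communities(net)
        table = centrality_table(net, assign)
        rs = []
        for _ in range(30):
            table.ei = rng.permutation(table.ei)
            rs.append(abs(severity_centrality_correlation(cohort2000, table)["mean"]["ei"][0]))
        assert np.mean(rs) < 0.35


class TestZScores:
    def test_z_scores_standardized(self, true_network, planted_spec):
        table = centrality_table(true_network, planted_spec.community_labels)
        for z in table.z.values():
            assert z.mean() == pytest.approx(0.0, abs=1e-12)
            assert z.std() == pytest.approx(1.0, abs=1e-12)
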