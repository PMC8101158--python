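#!/usr/bin/env python
"""Community structure, centrality and stability of the estimated network.

Bootstrapped walktrap communities (count distribution + item stability),
EI / bridge-EI / PC / PR centralities, edge-accuracy bootstrap, the
case-dropping CS coefficient, severity-centrality correlations, and an
example shortest path between two anxiety/depression items.
"""
import argparse
from pathlib import Path

import numpy as np

from symptomnet._utils import child_seed
from symptomnet.ggm import GGMConfig, estimate_network
from symptomnet.io import (read_cohort, write_centrality, write_communities,
                           write_stability)
from symptomnet.netanalysis import (bootstrap_communities, centrality_stability,
                                    centrality_table, edge_accuracy_bootstrap,
                                    severity_centrality_correlation, shortest_paths)

OUT = Path("results/analysis")


def main(seed: int = 0, B: int = 100) -> None:
    cohort = read_cohort(OUT / "cohort_reduced.csv", OUT / "cohort_reduced.json")
    fast = GGMConfig(estimator="glasso", n_lambda=20)

    part = bootstrap_communities(cohort, fast, B=B, seed=child_seed(seed, "comm"))
    print(f"walktrap: {part.n_communities} communities "
          f"(bootstrap median = {part.count_median:.0f}, SD = {part.count_sd:.2f}, "
          f"95% CI [{part.count_ci[0]:.2f}, {part.count_ci[1]:.2f}])")
    low_stab = [n for n, s in zip(cohort.item_names, part.item_stability) if s < 0.7]
    print(f"items with community stability < 0.7: {low_stab or 'none'}")

    net = estimate_network(cohort, GGMConfig(), correct_covariates=True)
    table = centrality_table(net, part.assignment)
    write_communities(part, net.nodes, OUT / "communities.tsv",
                      OUT / "communities_summary.json")
    write_centrality(table, OUT / "centrality.csv")
    order = np.argsort(-table.z["ei"])
    print("top-3 EI:", [net.nodes[i] for i in order[:3]])
    order_b = np.argsort(-table.bridge_ei)
    print("top-3 bridge EI:", [net.nodes[i] for i in order_b[:3]])

    stab = edge_accuracy_bootstrap(cohort, fast, B=B, seed=child_seed(seed, "edge"))
    cs = centrality_stability(cohort, fast, B=max(B // 2, 10),
                              seed=child_seed(seed, "cs"))
    stab.drop_proportions = cs.drop_proportions
    stab.correlation_quantiles = cs.correlation_quantiles
    stab.cs_coefficient = cs.cs_coefficient
    write_stability(stab, OUT / "stability.json")
    print(f"EI correlation-stability (CS) coefficient: {cs.cs_coefficient}")

    sev = severity_centrality_correlation(cohort, table)
    print(f"mean severity vs EI: r = {sev['mean']['ei'][0]:.2f} "
          f"(p = {sev['mean']['ei'][1]:.3f}); "
          f"SD vs EI: r = {sev['sd']['ei'][0]:.2f}")

    # example pathway query: first anxiety item to first depressive item
    src = next(n for n in net.nodes if n >= "item14")
    dst = net.nodes[0]
    path = shortest_paths(net, src, dst)
    print(f"shortest path {src} -> {dst}: {path.path} (distance {path.distance:.2f})")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("-B", type=int, default=100)
    args = ap.parse_args()
    main(args.seed, args.B)
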