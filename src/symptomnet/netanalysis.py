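"""Community structure, centrality and stability analysis of a symptom network.

Communities are found with the walktrap random-walk algorithm on absolute
edge weights (signed weights are kept for the centrality indices).  Node
importance is summarised by expected influence (EI, the signed one-step
strength), bridge expected influence (connection to other communities),
the participation coefficient (PC) and participation ratio (PR), and their
geometric mean.  Robustness is assessed by case-resampling bootstraps of the
whole estimation pipeline: community-count distributions, per-edge
confidence intervals, and the case-dropping correlation-stability (CS)
coefficient of the centrality ordering.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
from scipy import stats

from .ggm import GGMConfig, GGMNetwork, estimate_network
from .synthetic import SymptomCohort


@dataclass
class CommunityPartition:
    assignment: np.ndarray  # community id per node, 1-based
    n_communities: int
    bootstrap_counts: np.ndarray | None = None
    count_median: float | None = None
    count_sd: float | None = None
    count_ci: tuple[float, float] | None = None
    item_stability: np.ndarray | None = None
    n_failed: int = 0


@dataclass
class CentralityTable:
    nodes: list[str]
    ei: np.ndarray
    bridge_ei: np.ndarray
    pc: np.ndarray
    pr: np.ndarray
    pcpr: np.ndarray
    z: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class StabilityReport:
    edge_estimates: np.ndarray
    edge_ci_lower: np.ndarray
    edge_ci_upper: np.ndarray
    n_boot: int
    drop_proportions: np.ndarray | None = None
    correlation_quantiles: np.ndarray | None = None  # 5th pct of corr per proportion
    cs_coefficient: float | None = None


@dataclass
class PathResult:
    path: list[str] | None
    distance: float


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()  # population convention
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def walktrap_communities(net: GGMNetwork, steps: int = 4) -> np.ndarray:
    """Walktrap community detection on absolute edge weights.

    The dendrogram is cut at maximum modularity.  Isolated nodes become
    singleton communities; an empty network makes every node a singleton.
    Returns 1-based community ids.
    """
    W = np.abs(net.weights)
    p = W.shape[0]
    if not (W > 0).any():
        warnings.warn("network has no edges: every node is a singleton community",
                      stacklevel=2)
        return np.arange(1, p + 1)
    g = ig.Graph.Weighted_Adjacency(W.tolist(), mode="undirected", attr="weight", loops=False)
    dendro = g.community_walktrap(weights="weight", steps=steps)
    clustering = dendro.as_clustering()  # max-modularity cut
    return np.asarray(clustering.membership, dtype=int) + 1


def _stability_vs_reference(ref: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Per-node fraction of its reference-community co-members co-assigned
    with it in a replicate partition."""
    p = len(ref)
    out = np.zeros(p)
    for i in range(p):
        mates = np.flatnonzero((ref == ref[i]) & (np.arange(p) != i))
        if mates.size == 0:
            out[i] = 1.0
        else:
            out[i] = float(np.mean(member[mates] == member[i]))
    return out


def bootstrap_communities(cohort: SymptomCohort, config: GGMConfig | None = None,
                          B: int = 1000, seed: int = 0,
                          correct_covariates: bool = False) -> CommunityPartition:
    """Case-resampling bootstrap of the walktrap community count.

    Each replicate resamples subjects with replacement, re-estimates the
    network and re-runs walktrap.  Reports the full-sample assignment, the
    bootstrap median/SD/95% percentile CI of the community count, and per-item
    stability (fraction of replicates in which an item stays co-assigned with
    its full-sample community).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    config = config or GGMConfig()
    rng = np.random.default_rng(seed)
    full_net = estimate_network(cohort, config, correct_covariates=correct_covariates)
    full_assign = walktrap_communities(full_net)
    counts, stabilities = [], []
    n = cohort.n_subjects
    failed = 0
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        try:
            net_b = estimate_network(cohort.subset(rows), config,
                                     correct_covariates=correct_covariates)
        except Exception:
            failed += 1
            continue
        assign_b = walktrap_communities(net_b)
        counts.append(len(np.unique(assign_b)))
        stabilities.append(_stability_vs_reference(full_assign, assign_b))
    if failed > 0.05 * B:
        warnings.warn(f"{failed}/{B} bootstrap replicates failed", stacklevel=2)
    counts = np.asarray(counts, dtype=float)
    stab = np.mean(stabilities, axis=0) if stabilities else None
    return CommunityPartition(
        assignment=full_assign,
        n_communities=len(np.unique(full_assign)),
        bootstrap_counts=counts,
        count_median=float(np.median(counts)) if counts.size else None,
        count_sd=float(counts.std(ddof=1)) if counts.size > 1 else 0.0,
        count_ci=tuple(np.percentile(counts, [2.5, 97.5])) if counts.size else None,
        item_stability=stab,
        n_failed=failed,
    )


def expected_influence(net: GGMNetwork) -> np.ndarray:
    """EI_i = sum_j w_ij (signed one-step expected influence)."""
    return net.weights.sum(axis=1)


def bridge_expected_influence(net: GGMNetwork, partition: np.ndarray,
                              normalise: bool = True) -> np.ndarray:
    """Bridge EI: a node's summed signed weight to nodes outside its own
    community; the normalised variant divides by the number of such nodes."""
    partition = np.asarray(partition)
    p = net.n_nodes
    if partition.shape != (p,):
        raise ValueError("partition must cover all nodes")
    if len(np.unique(partition)) == 1:
        warnings.warn("single community: bridge EI is identically zero", stacklevel=2)
        return np.zeros(p)
    out = np.zeros(p)
    for i in range(p):
        outside = partition != partition[i]
        val = net.weights[i, outside].sum()
        if normalise:
            val /= outside.sum()
        out[i] = val
    return out


def participation_metrics(net: GGMNetwork, partition: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Participation coefficient, participation ratio and their geometric mean.

    With s_i = sum_j |w_ij| and kappa_ic = sum_{j in c} |w_ij|:
    PC_i = 1 - sum_c (kappa_ic/s_i)^2; PR_i = s_i^2 / sum_j w_ij^2.
    Isolated nodes get PC = PR = 0 by convention.
    """
    partition = np.asarray(partition)
    W = np.abs(net.weights)
    p = net.n_nodes
    if partition.shape != (p,):
        raise ValueError("partition must cover all nodes")
    s = W.sum(axis=1)
    sq = (W ** 2).sum(axis=1)
    pc = np.zeros(p)
    pr = np.zeros(p)
    for i in range(p):
        if s[i] == 0:
            continue
        kappas = np.array([W[i, partition == c].sum() for c in np.unique(partition)])
        pc[i] = 1.0 - float(((kappas / s[i]) ** 2).sum())
        pr[i] = s[i] ** 2 / sq[i]
    pcpr = np.sqrt(np.clip(pc, 0, None) * np.clip(pr, 0, None))
    return pc, pr, pcpr


def centrality_table(net: GGMNetwork, partition: np.ndarray,
                     normalise_bridge: bool = True) -> CentralityTable:
    """All centrality indices plus node-wise z-scores (z-scored after any
    combination, e.g. after the PC/PR geometric mean)."""
    ei = expected_influence(net)
    bei = bridge_expected_influence(net, partition, normalise=normalise_bridge)
    pc, pr, pcpr = participation_metrics(net, partition)
    z = {name: _zscore(v) for name, v in
         [("ei", ei), ("bridge_ei", bei), ("pc", pc), ("pr", pr), ("pcpr", pcpr)]}
    return CentralityTable(nodes=list(net.nodes), ei=ei, bridge_ei=bei,
                           pc=pc, pr=pr, pcpr=pcpr, z=z)


def edge_accuracy_bootstrap(cohort: SymptomCohort, config: GGMConfig | None = None,
                            B: int = 1000, seed: int = 0,
                            correct_covariates: bool = False) -> StabilityReport:
    """Nonparametric bootstrap of edge-weight accuracy: case-resample,
    re-estimate, 2.5/97.5 percentile interval per node pair."""
    if B < 2:
        raise ValueError("B must be >= 2")
    config = config or GGMConfig()
    rng = np.random.default_rng(seed)
    full_net = estimate_network(cohort, config, correct_covariates=correct_covariates)
    p = full_net.n_nodes
    n = cohort.n_subjects
    reps = []
    failed = 0
    for _ in range(B):
        rows = rng.integers(0, n, size=n)
        try:
            net_b = estimate_network(cohort.subset(rows), config,
                                     correct_covariates=correct_covariates)
        except Exception:
            failed += 1
            continue
        reps.append(net_b.weights[np.triu_indices(p, 1)])
    if failed > 0.05 * B:
        warnings.warn(f"{failed}/{B} bootstrap replicates failed", stacklevel=2)
    reps = np.asarray(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    return StabilityReport(
        edge_estimates=full_net.weights[np.triu_indices(p, 1)],
        edge_ci_lower=lo, edge_ci_upper=hi, n_boot=len(reps),
    )


def centrality_stability(cohort: SymptomCohort, config: GGMConfig | None = None,
                         drop_proportions: np.ndarray | None = None,
                         B: int = 250, seed: int = 0,
                         correct_covariates: bool = False) -> StabilityReport:
    """Case-dropping bootstrap of EI centrality: the CS coefficient.

    For each drop proportion, B subsamples are drawn without replacement,
    the network re-estimated, and subsample EI correlated (Pearson) with the
    full-sample EI.  CS = the largest proportion at which at least 95% of
    correlations reach 0.7, with all smaller proportions also passing; 0 if
    none does.  Proportions leaving fewer than 3*p subjects are skipped.
    """
    config = config or GGMConfig()
    if drop_proportions is None:
        drop_proportions = np.round(np.arange(0.05, 0.80, 0.05), 10)
    drop_proportions = np.asarray(drop_proportions, dtype=float)
    if ((drop_proportions <= 0) | (drop_proportions >= 1)).any():
        raise ValueError("drop proportions must lie in (0,1)")
    rng = np.random.default_rng(seed)
    full_net = estimate_network(cohort, config, correct_covariates=correct_covariates)
    full_ei = expected_influence(full_net)
    n, p = cohort.n_subjects, full_net.n_nodes
    q05 = np.full(drop_proportions.size, np.nan)
    for d, prop in enumerate(drop_proportions):
        m = int(round(n * (1 - prop)))
        if m < 3 * p:
            warnings.warn(f"drop proportion {prop:.2f} leaves {m} < 3p subjects; skipped",
                          stacklevel=2)
            continue
        corrs = []
        for _ in range(B):
            rows = rng.choice(n, size=m, replace=False)
            try:
                net_b = estimate_network(cohort.subset(rows), config,
                                         correct_covariates=correct_covariates)
            except Exception:
                continue
            ei_b = expected_influence(net_b)
            if np.std(ei_b) == 0 or np.std(full_ei) == 0:
                corrs.append(0.0)
            else:
                corrs.append(float(np.corrcoef(full_ei, ei_b)[0, 1]))
        q05[d] = np.quantile(corrs, 0.05) if corrs else np.nan
    cs = 0.0
    for d, prop in enumerate(drop_proportions):
        if np.isnan(q05[d]):
            break
        if q05[d] >= 0.7:
            cs = float(prop)
        else:
            break
    return StabilityReport(
        edge_estimates=full_net.weights[np.triu_indices(p, 1)],
        edge_ci_lower=np.array([]), edge_ci_upper=np.array([]), n_boot=B,
        drop_proportions=drop_proportions, correlation_quantiles=q05,
        cs_coefficient=cs,
    )


def shortest_paths(net: GGMNetwork, source: str, target: str) -> PathResult:
    """Dijkstra shortest path with edge distance 1/|w_ij|."""
    if source not in net.nodes or target not in net.nodes:
        raise KeyError("source and target must be network nodes")
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for a, b, w in net.edge_list():
        g.add_edge(a, b, dist=1.0 / abs(w))
    try:
        path = nx.dijkstra_path(g, source, target, weight="dist")
        dist = nx.dijkstra_path_length(g, source, target, weight="dist")
    except nx.NetworkXNoPath:
        return PathResult(path=None, distance=np.inf)
    return PathResult(path=path, distance=float(dist))


def severity_centrality_correlation(cohort: SymptomCohort, table: CentralityTable
                                    ) -> dict[str, dict[str, tuple[float, float]]]:
    """Pearson r (and p) between item severity moments (mean, SD) and the EI
    and PC/PR centralities.  Undefined correlations (constant index) are
    reported as (nan, nan)."""
    means = cohort.items.mean(axis=0)
    sds = cohort.items.std(axis=0, ddof=1)
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for mom_name, mom in [("mean", means), ("sd", sds)]:
        out[mom_name] = {}
        for idx_name, idx in [("ei", table.ei), ("pcpr", table.pcpr)]:
            if np.std(idx) == 0 or np.std(mom) == 0:
                out[mom_name][idx_name] = (np.nan, np.nan)
            else:
                r, pv = stats.pearsonr(mom, idx)
                out[mom_name][idx_name] = (float(r), float(pv))
    return out
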