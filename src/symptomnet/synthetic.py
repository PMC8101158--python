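"""Synthetic ordinal symptom cohorts with a planted partial-correlation network.

The generator emulates a pooled primary-care depression trial cohort: ordinal
symptom items (BDI-II-like, 0-3; CIS-R-subscale-like, 0-4) whose latent
structure is a Gaussian graphical model with three communities (anxiety,
depressive-cognitive, depressive-physical), designated bridge edges between
communities, optional redundant item pairs (multi-collinearity), two duration
covariates shifting item means, and a continuous follow-up outcome driven by a
sparse subset of items.  Everything downstream (screening, network estimation,
community/centrality analysis, group comparison, prognosis) can therefore be
checked against recoverable ground truth.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from ._utils import child_seed, partial_correlations


@dataclass
class NetworkSpec:
    """Ground-truth partial-correlation network with community structure.

    Parameters
    ----------
    n_nodes : total number of symptom items.
    community_labels : community id (1..C) per node.
    within_weight : partial correlation planted on within-community edges.
    bridge_edges : ``(i, j, weight)`` cross-community edges.
    within_density : fraction of within-community pairs that receive an edge.
    base_diagonal : diagonal constant of the precision matrix; partial
        correlations are invariant to it.
    seed : selects which within-community pairs are connected.
    """

    n_nodes: int
    community_labels: np.ndarray
    within_weight: float = 0.2
    bridge_edges: list[tuple[int, int, float]] = field(default_factory=list)
    within_density: float = 0.45
    base_diagonal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.community_labels = np.asarray(self.community_labels, dtype=int)
        if self.community_labels.shape != (self.n_nodes,):
            raise ValueError("community_labels must have one entry per node")
        if self.base_diagonal <= 0:
            raise ValueError("base_diagonal must be positive")
        for i, j, _ in self.bridge_edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            if self.community_labels[i] == self.community_labels[j]:
                raise ValueError(f"bridge edge ({i},{j}) is within a community")


@dataclass
class CohortSpec:
    """Sampling plan for one synthetic cohort drawn over a :class:`NetworkSpec`."""

    n_subjects: int
    likert_levels: np.ndarray | int = 4
    thresholds: list[np.ndarray] | None = None
    redundant_pairs: list[tuple[int, int]] = field(default_factory=list)
    outcome_betas: np.ndarray | None = None
    outcome_noise_sd: float = 1.0
    duration_effect: float = 0.1
    redundancy_noise_sd: float = 0.2
    group_delta: float | np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")

    def levels_for(self, n_items: int) -> np.ndarray:
        lv = self.likert_levels
        if np.isscalar(lv):
            lv = np.full(n_items, int(lv))
        lv = np.asarray(lv, dtype=int)
        if (lv < 2).any():
            raise ValueError("likert_levels must be >= 2")
        return lv


@dataclass
class SymptomCohort:
    """Subject x item ordinal matrix plus covariates, outcome and labels."""

    items: np.ndarray
    item_names: list[str]
    item_ranges: list[tuple[int, int]]
    covariates: np.ndarray
    outcome: np.ndarray
    group: np.ndarray | None = None
    study: np.ndarray | None = None
    covariate_names: list[str] = field(default_factory=lambda: ["dur_depression", "dur_anxiety"])

    @property
    def n_subjects(self) -> int:
        return self.items.shape[0]

    @property
    def n_items(self) -> int:
        return self.items.shape[1]

    def validate(self) -> None:
        if self.items.shape != (len(self.outcome), len(self.item_names)):
            raise ValueError("inconsistent cohort dimensions")
        if np.isnan(self.items).any():
            raise ValueError("missing item values")
        if not np.all(np.isfinite(self.outcome)):
            raise ValueError("outcome must be finite")
        for k, (lo, hi) in enumerate(self.item_ranges):
            col = self.items[:, k]
            if col.size and (col.min() < lo or col.max() > hi):
                raise ValueError(f"item {self.item_names[k]} outside declared range [{lo},{hi}]")

    def subset(self, rows: np.ndarray) -> "SymptomCohort":
        return SymptomCohort(
            items=self.items[rows],
            item_names=list(self.item_names),
            item_ranges=list(self.item_ranges),
            covariates=self.covariates[rows],
            outcome=self.outcome[rows],
            group=None if self.group is None else self.group[rows],
            study=None if self.study is None else self.study[rows],
            covariate_names=list(self.covariate_names),
        )


def planted_weights(spec: NetworkSpec) -> np.ndarray:
    """The planted partial-correlation matrix P (zero diagonal)."""
    explicit = getattr(spec, "_weights", None)
    if explicit is not None:
        return explicit
    p = spec.n_nodes
    P = np.zeros((p, p))
    rng = np.random.default_rng(spec.seed)
    labels = spec.community_labels
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        pairs = [(a, b) for ai, a in enumerate(idx) for b in idx[ai + 1:]]
        if not pairs:
            continue
        n_keep = int(round(spec.within_density * len(pairs)))
        keep = rng.choice(len(pairs), size=n_keep, replace=False)
        for k in keep:
            a, b = pairs[k]
            P[a, b] = P[b, a] = spec.within_weight
    for i, j, w in spec.bridge_edges:
        P[i, j] = P[j, i] = w
    return P


def build_precision_matrix(spec: NetworkSpec) -> tuple[np.ndarray, np.ndarray]:
    """Construct the precision matrix K and its implied partial correlations.

    K = base_diagonal * (I - P) with P the planted partial-correlation matrix,
    so that -k_ij / sqrt(k_ii k_jj) reproduces the planted weights exactly.

    Raises
    ------
    ValueError
        if the implied matrix is not positive definite (reports the smallest
        eigenvalue).
    """
    P = planted_weights(spec)
    K = spec.base_diagonal * (np.eye(spec.n_nodes) - P)
    eigmin = float(np.linalg.eigvalsh(K).min())
    if eigmin <= 1e-10:
        raise ValueError(
            f"network spec implies a non-positive-definite precision matrix "
            f"(smallest eigenvalue {eigmin:.3e})"
        )
    return K, partial_correlations(K)


def latent_correlation(spec: NetworkSpec) -> np.ndarray:
    """Marginal correlation matrix of the latent Gaussian implied by a NetworkSpec."""
    K, _ = build_precision_matrix(spec)
    sigma = np.linalg.inv(K)
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def equiprobable_thresholds(levels: int) -> np.ndarray:
    """Standard-normal cut points giving equal category probabilities."""
    return stats.norm.ppf(np.arange(1, levels) / levels)


def _discretize(latent: np.ndarray, thresholds: list[np.ndarray]) -> np.ndarray:
    out = np.empty_like(latent, dtype=int)
    for k, cuts in enumerate(thresholds):
        if not np.all(np.diff(cuts) > 0):
            raise ValueError(f"thresholds for item {k} must be strictly increasing")
        out[:, k] = np.searchsorted(cuts, latent[:, k], side="left")
    return out


def generate_cohort(net: NetworkSpec, cohort: CohortSpec) -> SymptomCohort:
    """Sample an ordinal symptom cohort from the planted latent network.

    A latent multivariate normal draw (unit variances) is shifted by the
    duration covariates, redundant items are overwritten by their source
    latent plus noise, and each latent column is cut at the item thresholds.
    The outcome is a sparse linear function of the ordinal items plus noise;
    a remitter/persister label is derived from a follow-up sum-score analogue
    thresholded at < 10.
    """
    p = net.n_nodes
    levels = cohort.levels_for(p)
    rng = np.random.default_rng(cohort.seed)
    sigma = latent_correlation(net)
    chol = np.linalg.cholesky(sigma)

    n = cohort.n_subjects
    latent = rng.standard_normal((n, p)) @ chol.T
    durations = rng.lognormal(mean=0.0, sigma=0.5, size=(n, 2))
    if n:
        dz = (durations - durations.mean(0)) / durations.std(0)
        latent = latent + cohort.duration_effect * dz.sum(axis=1, keepdims=True)

    for src, dup in cohort.redundant_pairs:
        latent[:, dup] = latent[:, src] + rng.normal(0.0, cohort.redundancy_noise_sd, size=n)

    thresholds = cohort.thresholds
    if thresholds is None:
        thresholds = [equiprobable_thresholds(lv) for lv in levels]
    items = _discretize(latent, thresholds) if n else np.zeros((0, p), dtype=int)
    for k in range(p):
        if n and len(np.unique(items[:, k])) < 2:
            warnings.warn(f"item {k} is degenerate (single observed category)", stacklevel=2)

    betas = cohort.outcome_betas
    if betas is None:
        betas = np.zeros(p)
    betas = np.asarray(betas, dtype=float)
    outcome = items @ betas + rng.normal(0.0, cohort.outcome_noise_sd, size=n)

    # Follow-up sum-score analogue: baseline total shrunk by a per-subject
    # recovery factor; remission below a total of 10, mirroring the usual
    # remission rule for a 0-63 depression total.
    totals = items.sum(axis=1)
    recovery = rng.uniform(0.1, 0.9, size=n)
    follow = totals * recovery
    group = np.where(follow < 10, "remitter", "persister") if n else None

    names = [f"item{k:02d}" for k in range(p)]
    ranges = [(0, int(lv) - 1) for lv in levels]
    coh = SymptomCohort(
        items=items.astype(float),
        item_names=names,
        item_ranges=ranges,
        covariates=durations,
        outcome=outcome,
        group=group,
    )
    coh.validate()
    return coh


def perturb_network(net: NetworkSpec, group_delta: float | np.ndarray) -> np.ndarray:
    """Partial-correlation matrix for group 2: scalar delta scales all edges by
    (1 + delta); a matrix delta is added edgewise."""
    _, P = build_precision_matrix(net)
    if np.isscalar(group_delta):
        P2 = P * (1.0 + float(group_delta))
    else:
        delta = np.asarray(group_delta, dtype=float)
        P2 = P + (delta + delta.T) / 2.0 * (1 - np.eye(net.n_nodes))
    eigmin = float(np.linalg.eigvalsh(np.eye(net.n_nodes) - P2).min())
    if eigmin <= 1e-10:
        raise ValueError(
            f"group perturbation breaks positive definiteness (eigmin {eigmin:.3e})"
        )
    return P2


def generate_two_groups(net: NetworkSpec, cohort: CohortSpec) -> tuple[SymptomCohort, SymptomCohort]:
    """Two cohorts for the network comparison test.

    Group 1 is drawn from ``net``; group 2 from the same spec with edge
    weights perturbed by ``cohort.group_delta``.  A zero delta makes both
    groups draws from the identical distribution (the permutation null).
    """
    if cohort.group_delta is None:
        raise ValueError("group_delta must be set (possibly 0) for two-group generation")
    seed1 = child_seed(cohort.seed, "group1")
    seed2 = child_seed(cohort.seed, "group2")
    c1 = generate_cohort(net, replace(cohort, seed=seed1))

    P2 = perturb_network(net, cohort.group_delta)
    net2 = _FixedWeightSpec(net, P2)
    c2 = generate_cohort(net2, replace(cohort, seed=seed2))
    c1.group = np.full(c1.n_subjects, "group1")
    c2.group = np.full(c2.n_subjects, "group2")
    return c1, c2


class _FixedWeightSpec(NetworkSpec):
    """NetworkSpec whose partial-correlation matrix is given explicitly."""

    def __init__(self, base: NetworkSpec, weights: np.ndarray):
        super().__init__(
            n_nodes=base.n_nodes,
            community_labels=base.community_labels.copy(),
            within_weight=base.within_weight,
            bridge_edges=list(base.bridge_edges),
            within_density=base.within_density,
            base_diagonal=base.base_diagonal,
            seed=base.seed,
        )
        self._weights = weights


def default_network(n_nodes: int = 20, within_weight: float = 0.2,
                    within_density: float = 0.45, bridge_weight: float = 0.15,
                    seed: int = 7) -> NetworkSpec:
    """Study-condition network: three contiguous communities of near-equal
    size, one bridge edge between each pair of communities."""
    sizes = [n_nodes // 3 + (1 if r < n_nodes % 3 else 0) for r in range(3)]
    labels = np.repeat([1, 2, 3], sizes)
    starts = np.cumsum([0] + sizes[:-1])
    ends = np.cumsum(sizes) - 1
    bridges = [
        (int(ends[0]), int(starts[1]), bridge_weight),
        (int(ends[1]), int(starts[2]), bridge_weight),
        (int(ends[2]), int(starts[0]), bridge_weight),
    ]
    return NetworkSpec(
        n_nodes=n_nodes,
        community_labels=labels,
        within_weight=within_weight,
        bridge_edges=bridges,
        within_density=within_density,
        seed=seed,
    )


def bridge_nodes(spec: NetworkSpec) -> list[int]:
    """Nodes incident to at least one planted cross-community edge."""
    out: set[int] = set()
    for i, j, _ in spec.bridge_edges:
        out.add(i)
        out.add(j)
    return sorted(out)


def default_cohort(n_subjects: int = 2000, n_nodes: int = 20, seed: int = 0,
                   outcome_items: dict[int, float] | None = None,
                   redundant_pairs: list[tuple[int, int]] | None = None) -> CohortSpec:
    """Study-condition cohort: first two communities BDI-like (4 levels),
    anxiety community CIS-R-like (5 levels); outcome loads on a sparse set."""
    levels = np.full(n_nodes, 4)
    levels[2 * n_nodes // 3:] = 5
    betas = np.zeros(n_nodes)
    if outcome_items is None:
        outcome_items = {1: 0.5, n_nodes // 2: 0.5, n_nodes - 2: 0.5}
    for k, b in outcome_items.items():
        betas[k] = b
    return CohortSpec(
        n_subjects=n_subjects,
        likert_levels=levels,
        redundant_pairs=redundant_pairs or [],
        outcome_betas=betas,
        seed=seed,
    )
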