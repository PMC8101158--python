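"""Gaussian graphical model estimation.

The estimator mirrors the conservative unregularized workflow used in recent
psychometric network studies: a graphical-lasso path (100 penalties by
default) proposes candidate edge sets; each candidate is re-fitted without
regularisation as a concentration-graph maximum-likelihood model; models are
scored by the Extended Bayesian Information Criterion (EBIC); and a greedy
stepwise search then adds/removes single edges while the EBIC keeps
improving.  Edge weights are partial correlations derived from the final
precision matrix.  Duration-of-illness covariates can be conditioned on by
including them as nodes during estimation and dropping them from the report.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso

from ._utils import is_symmetric, nearest_psd, partial_correlations
from .preprocess import spearman_matrix
from .synthetic import SymptomCohort


@dataclass
class GGMConfig:
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    gamma: float = 0.5
    max_search_steps: int = 200
    tol: float = 1e-7
    glasso_tol: float = 1e-5
    estimator: str = "search"  # "search" | "path" | "glasso"

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class GGMNetwork:
    nodes: list[str]
    weights: np.ndarray  # symmetric partial-correlation matrix, zero diagonal
    n: int
    estimator: str
    gamma: float
    covariates_corrected: list[str] = field(default_factory=list)
    precision: np.ndarray | None = None
    ebic: float | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        if not is_symmetric(W, tol=1e-8):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diag(W)).max() > 1e-12:
            raise ValueError("weights must have zero diagonal")
        if np.abs(W).max() >= 1.0:
            raise ValueError("partial correlations must have magnitude < 1")
        self.weights = W

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_list(self) -> list[tuple[str, str, float]]:
        out = []
        p = self.n_nodes
        for i in range(p):
            for j in range(i + 1, p):
                if self.weights[i, j] != 0:
                    out.append((self.nodes[i], self.nodes[j], float(self.weights[i, j])))
        return out


def gaussian_loglik(S: np.ndarray, K: np.ndarray, n: int) -> float:
    """Profile Gaussian log-likelihood of a concentration matrix K against the
    (Spearman) correlation matrix S treated as the sample covariance."""
    p = S.shape[0]
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    return 0.5 * n * (logdet - float(np.sum(S * K)) - p * np.log(2 * np.pi))


def ebic(loglik: float, n_edges: int, n: int, p: int, gamma: float) -> float:
    """EBIC = -2*loglik + E*log(n) + 4*gamma*E*log(p)."""
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    return -2.0 * loglik + n_edges * np.log(n) + 4.0 * gamma * n_edges * np.log(p)


def _adjacency(K: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    A = np.abs(K) > atol
    np.fill_diagonal(A, False)
    return A


def _n_edges(A: np.ndarray) -> int:
    return int(np.triu(A, 1).sum())


def glasso_path(S: np.ndarray, n: int, config: GGMConfig | None = None
                ) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Graphical-lasso solutions along a log-spaced penalty path.

    The path runs from lambda_max (the smallest penalty giving the empty
    graph, max |off-diagonal of S|) down by ``lambda_min_ratio``.  Points that
    fail to converge are dropped with a warning.
    Returns ``(lambda, precision, adjacency)`` triples.
    """
    config = config or GGMConfig()
    S = np.asarray(S, dtype=float)
    if not is_symmetric(S, tol=1e-8):
        raise ValueError("S must be symmetric")
    p = S.shape[0]
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: estimation may be unstable", stacklevel=2)
    if np.linalg.eigvalsh(S).min() < -1e-8:
        S = nearest_psd(S)
    lam_max = np.abs(S - np.diag(np.diag(S))).max()
    if lam_max == 0:
        lam_max = 1e-3
    lams = np.logspace(np.log10(lam_max), np.log10(lam_max * config.lambda_min_ratio),
                       config.n_lambda)
    out = []
    for lam in lams:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, K = graphical_lasso(S, alpha=float(lam), tol=config.glasso_tol,
                                       enet_tol=config.glasso_tol, max_iter=200)
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"glasso failed at lambda={lam:.4g}: {exc}", stacklevel=2)
            continue
        K = (K + K.T) / 2.0
        out.append((float(lam), K, _adjacency(K, atol=1e-6)))
    return out


def refit_unregularized(S: np.ndarray, n: int, adjacency: np.ndarray,
                        tol: float = 1e-8, max_cycles: int = 500,
                        sigma_init: np.ndarray | None = None) -> np.ndarray:
    """Concentration-graph MLE: maximize the Gaussian likelihood subject to
    zero precision entries off the given adjacency.

    Uses cyclic regression updates on the covariance (Hastie, Tibshirani &
    Friedman's graphical-model MLE algorithm).  The fitted covariance matches
    S exactly on the diagonal and on adjacency entries; the precision is
    exactly zero elsewhere.
    """
    S = np.asarray(S, dtype=float)
    A = np.asarray(adjacency, dtype=bool)
    p = S.shape[0]
    if A.shape != (p, p) or not np.array_equal(A, A.T) or A.diagonal().any():
        raise ValueError("adjacency must be symmetric with zero diagonal")
    if not A.any():
        return np.diag(1.0 / np.diag(S))
    if _n_edges(A) == p * (p - 1) // 2:
        return np.linalg.inv(S)

    W = S.copy() if sigma_init is None else sigma_init.copy()
    betas = [None] * p
    for cycle in range(max_cycles):
        delta = 0.0
        for j in range(p):
            nz = np.flatnonzero(A[j])
            idx = np.delete(np.arange(p), j)
            w12_new = np.zeros(p)
            if nz.size:
                W11 = W[np.ix_(nz, nz)]
                beta_nz = np.linalg.solve(W11, S[nz, j])
                # propagate through all other variables: w12 = W11_full @ beta
                full = W[np.ix_(idx, nz)] @ beta_nz
                w12_new[idx] = full
                b = np.zeros(p)
                b[nz] = beta_nz
                betas[j] = b
            else:
                betas[j] = np.zeros(p)
            w12_new[j] = S[j, j]
            delta = max(delta, np.abs(W[:, j] - w12_new).max())
            W[:, j] = w12_new
            W[j, :] = w12_new
        if delta < tol:
            break
    else:
        resid = _moment_gap(S, W, A)
        raise RuntimeError(
            f"concentration-graph MLE did not converge in {max_cycles} cycles "
            f"(moment gap {resid:.3e})"
        )

    K = np.zeros((p, p))
    for j in range(p):
        b = betas[j]
        k_jj = 1.0 / (S[j, j] - float(W[:, j] @ b) + b[j] * W[j, j])
        # b[j] is zero by construction (no self edge), so the correction term
        # vanishes; kept for clarity of the partitioned-inverse identity.
        K[j, j] = k_jj
        K[:, j] -= b * k_jj
        K[j, j] = k_jj
    K = (K + K.T) / 2.0
    K[~A & ~np.eye(p, dtype=bool)] = 0.0
    return K


def _moment_gap(S: np.ndarray, sigma: np.ndarray, A: np.ndarray) -> float:
    mask = A | np.eye(S.shape[0], dtype=bool)
    return float(np.abs((S - sigma))[mask].max())


def _refit_and_score(S: np.ndarray, n: int, A: np.ndarray, gamma: float
                     ) -> tuple[np.ndarray, float]:
    K = refit_unregularized(S, n, A)
    ll = gaussian_loglik(S, K, n)
    return K, ebic(ll, _n_edges(A), n, S.shape[0], gamma)


def ggm_model_select(S: np.ndarray, n: int, config: GGMConfig | None = None,
                     nodes: list[str] | None = None) -> GGMNetwork:
    """EBIC model search for an unregularized GGM.

    1. Run the glasso path (``config.n_lambda`` models).
    2. Re-fit every distinct edge set without regularisation; score by EBIC.
    3. From the best-scoring model, greedily add/remove single edges while
       EBIC strictly decreases (ties prefer removals, then lowest (i,j)).

    With ``config.estimator='path'`` step 3 is skipped; with ``'glasso'`` the
    regularized precision at the EBIC-optimal penalty is returned directly.
    """
    config = config or GGMConfig()
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    nodes = nodes or [f"v{i}" for i in range(p)]
    path = glasso_path(S, n, config)
    if not path:
        raise RuntimeError("glasso path produced no converged models")

    if config.estimator == "glasso":
        best = min(path, key=lambda t: ebic(gaussian_loglik(S, t[1], n),
                                            _n_edges(t[2]), n, p, config.gamma))
        K = best[1]
        score = ebic(gaussian_loglik(S, K, n), _n_edges(_adjacency(K, 1e-6)), n, p, config.gamma)
        return GGMNetwork(nodes=nodes, weights=partial_correlations(K), n=n,
                          estimator="glasso-EBIC", gamma=config.gamma,
                          precision=K, ebic=float(score))

    seen: set[bytes] = set()
    best_A, best_K, best_score = None, None, np.inf
    for _, _, A in path:
        key = np.packbits(A).tobytes()
        if key in seen:
            continue
        seen.add(key)
        try:
            K, score = _refit_and_score(S, n, A, config.gamma)
        except RuntimeError:
            continue
        if score < best_score - 1e-12:
            best_A, best_K, best_score = A.copy(), K, score
    if best_A is None:
        raise RuntimeError("no refit converged along the path")

    flagged = False
    if config.estimator == "search":
        steps = 0
        while steps < config.max_search_steps:
            steps += 1
            moves = []
            for i in range(p):
                for j in range(i + 1, p):
                    A_try = best_A.copy()
                    is_removal = A_try[i, j]
                    A_try[i, j] = A_try[j, i] = not A_try[i, j]
                    try:
                        K_try, score_try = _refit_and_score(S, n, A_try, config.gamma)
                    except RuntimeError:
                        continue
                    if score_try < best_score - 1e-10:
                        moves.append((score_try, 0 if is_removal else 1, i, j, A_try, K_try))
            if not moves:
                break
            moves.sort(key=lambda m: (m[0], m[1], m[2], m[3]))
            best_score, _, _, _, best_A, best_K = (
                moves[0][0], moves[0][1], moves[0][2], moves[0][3], moves[0][4], moves[0][5])
        else:
            flagged = True
            warnings.warn("stepwise search hit max_search_steps; returning best so far",
                          stacklevel=2)

    tag = "unregularized-search" if config.estimator == "search" else "unregularized-path"
    if flagged:
        tag += "-truncated"
    return GGMNetwork(nodes=nodes, weights=partial_correlations(best_K), n=n,
                      estimator=tag, gamma=config.gamma, precision=best_K,
                      ebic=float(best_score))


def glasso_fixed(S: np.ndarray, n: int, lam: float, config: GGMConfig | None = None,
                 nodes: list[str] | None = None) -> GGMNetwork:
    """Single graphical-lasso fit at a fixed penalty (fast permutation mode)."""
    config = config or GGMConfig()
    S = np.asarray(S, dtype=float)
    if np.linalg.eigvalsh(S).min() < -1e-8:
        S = nearest_psd(S)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, K = graphical_lasso(S, alpha=float(lam), tol=config.glasso_tol,
                               enet_tol=config.glasso_tol, max_iter=200)
    K = (K + K.T) / 2.0
    nodes = nodes or [f"v{i}" for i in range(S.shape[0])]
    return GGMNetwork(nodes=nodes, weights=partial_correlations(K), n=n,
                      estimator="glasso-fixed", gamma=config.gamma, precision=K)


def select_lambda(S: np.ndarray, n: int, config: GGMConfig | None = None) -> float:
    """EBIC-optimal penalty on the glasso path (used by the fixed-λ mode)."""
    config = config or GGMConfig()
    path = glasso_path(S, n, config)
    p = S.shape[0]
    best = min(path, key=lambda t: ebic(gaussian_loglik(S, t[1], n),
                                        _n_edges(t[2]), n, p, config.gamma))
    return best[0]


def estimate_network(cohort: SymptomCohort, config: GGMConfig | None = None,
                     correct_covariates: bool = True) -> GGMNetwork:
    """Estimate the symptom network from a cohort.

    The Spearman correlation matrix over items (plus, when
    ``correct_covariates``, the duration covariates as extra nodes) feeds the
    EBIC model search; covariate rows/columns are dropped from the reported
    network so item edges are conditioned on the covariates.
    """
    config = config or GGMConfig()
    X = cohort.items
    names = list(cohort.item_names)
    n_cov = 0
    if correct_covariates and cohort.covariates is not None and cohort.covariates.size:
        cov = cohort.covariates
        keep = [k for k in range(cov.shape[1]) if np.std(cov[:, k]) > 0]
        dropped = [cohort.covariate_names[k] for k in range(cov.shape[1]) if k not in keep]
        if dropped:
            warnings.warn(f"constant covariate(s) dropped: {dropped}", stacklevel=2)
        if keep:
            X = np.column_stack([X, cov[:, keep]])
            names = names + [cohort.covariate_names[k] for k in keep]
            n_cov = len(keep)
    S = spearman_matrix(X, names)
    net = ggm_model_select(S, cohort.n_subjects, config, nodes=names)
    if n_cov:
        p_items = len(names) - n_cov
        W = net.weights[:p_items, :p_items]
        K = None if net.precision is None else net.precision[:p_items, :p_items]
        return GGMNetwork(nodes=names[:p_items], weights=W, n=net.n,
                          estimator=net.estimator, gamma=net.gamma,
                          covariates_corrected=names[p_items:],
                          precision=K, ebic=net.ebic)
    return net
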