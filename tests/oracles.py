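"""Independent brute-force reference implementations used only by tests.

Every function here is written as directly as possible from the defining
formula or by exhaustive enumeration, deliberately sharing no code with the
package implementations it checks.
"""
from __future__ import annotations

import itertools

import numpy as np


def partial_corr_by_regression(sigma: np.ndarray, i: int, j: int) -> float:
    """Partial correlation of (i, j) given the rest, from the covariance, via
    the conditional-covariance (Schur complement) definition."""
    p = sigma.shape[0]
    rest = [k for k in range(p) if k not in (i, j)]
    A = sigma[np.ix_([i, j], [i, j])]
    B = sigma[np.ix_([i, j], rest)]
    D = sigma[np.ix_(rest, rest)]
    cond = A - B @ np.linalg.solve(D, B.T)
    return cond[0, 1] / np.sqrt(cond[0, 0] * cond[1, 1])


def spearman_bruteforce(X: np.ndarray) -> np.ndarray:
    """Rank (average ranks for ties) each column, then Pearson."""
    n, p = X.shape
    ranks = np.empty_like(X, dtype=float)
    for k in range(p):
        col = X[:, k]
        order = np.argsort(col, kind="stable")
        r = np.empty(n)
        pos = 0
        while pos < n:
            end = pos
            while end + 1 < n and col[order[end + 1]] == col[order[pos]]:
                end += 1
            avg = (pos + end) / 2.0 + 1.0
            for t in range(pos, end + 1):
                r[order[t]] = avg
            pos = end + 1
        ranks[:, k] = r
    out = np.eye(p)
    for a in range(p):
        for b in range(a + 1, p):
            x, y = ranks[:, a], ranks[:, b]
            xc, yc = x - x.mean(), y - y.mean()
            out[a, b] = out[b, a] = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
    return out


def expected_influence_loop(W: np.ndarray) -> np.ndarray:
    p = W.shape[0]
    out = np.zeros(p)
    for i in range(p):
        for j in range(p):
            if i != j:
                out[i] += W[i, j]
    return out


def bridge_ei_loop(W: np.ndarray, comm: np.ndarray, normalise: bool) -> np.ndarray:
    p = W.shape[0]
    out = np.zeros(p)
    for i in range(p):
        acc, n_out = 0.0, 0
        for j in range(p):
            if j != i and comm[j] != comm[i]:
                acc += W[i, j]
                n_out += 1
        out[i] = acc / n_out if (normalise and n_out) else acc
    return out


def participation_loop(W: np.ndarray, comm: np.ndarray):
    p = W.shape[0]
    pc = np.zeros(p)
    pr = np.zeros(p)
    for i in range(p):
        s = sum(abs(W[i, j]) for j in range(p) if j != i)
        sq = sum(W[i, j] ** 2 for j in range(p) if j != i)
        if s == 0:
            continue
        acc = 0.0
        for c in set(comm.tolist()):
            kappa = sum(abs(W[i, j]) for j in range(p) if j != i and comm[j] == c)
            acc += (kappa / s) ** 2
        pc[i] = 1.0 - acc
        pr[i] = s * s / sq
    return pc, pr


def global_strength_loop(W: np.ndarray) -> float:
    p = W.shape[0]
    total = 0.0
    for i in range(p):
        for j in range(i + 1, p):
            total += abs(W[i, j])
    return total


def shortest_path_enumerate(W: np.ndarray, src: int, dst: int):
    """Exhaustive simple-path search with distance 1/|w|; returns
    (best path, best distance)."""
    p = W.shape[0]
    best, best_d = None, np.inf
    nodes = [k for k in range(p) if k not in (src, dst)]
    for r in range(len(nodes) + 1):
        for mids in itertools.permutations(nodes, r):
            path = (src,) + mids + (dst,)
            d = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if W[a, b] == 0:
                    ok = False
                    break
                d += 1.0 / abs(W[a, b])
            if ok and d < best_d:
                best, best_d = list(path), d
    return best, best_d


def glasso_objective_minimize(S: np.ndarray, lam: float, n_iter: int = 200000,
                              step: float = 5e-4) -> np.ndarray:
    """Direct proximal-gradient minimization of the graphical-lasso objective
    tr(SK) - logdet K + lam * ||K||_{1,off} over symmetric positive definite K."""
    p = S.shape[0]
    K = np.eye(p)
    off = ~np.eye(p, dtype=bool)
    for _ in range(n_iter):
        grad = S - np.linalg.inv(K)
        K_new = K - step * grad
        K_new[off] = np.sign(K_new[off]) * np.maximum(np.abs(K_new[off]) - step * lam, 0.0)
        K_new = (K_new + K_new.T) / 2.0
        if np.linalg.eigvalsh(K_new).min() <= 1e-8:
            step *= 0.5
            continue
        if np.abs(K_new - K).max() < 1e-12:
            K = K_new
            break
        K = K_new
    return K


def dependent_corr_permutation_p(x: np.ndarray, y: np.ndarray, z: np.ndarray,
                                 n_perm: int = 2000, seed: int = 0) -> float:
    """Permutation oracle for H0: cor(x,z) = cor(y,z) with (x, y) exchangeable:
    randomly swap x/y within subjects and recompute the correlation difference.
    Spearman correlations, matching the implementation under test."""
    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    obs = abs(spearmanr(x, z).statistic - spearmanr(y, z).statistic)
    n = len(x)
    count = 0
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        xs = np.where(swap, y, x)
        ys = np.where(swap, x, y)
        stat = abs(spearmanr(xs, z).statistic - spearmanr(ys, z).statistic)
        if stat >= obs:
            count += 1
    return (1 + count) / (1 + n_perm)


def shapley_exact_linear(coef: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Closed-form Shapley values of a linear model with independent features
    and the empirical background: phi_j(x) = beta_j * (x_j - mean(X_j))."""
    return coef[None, :] * (X - X.mean(axis=0)[None, :])
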