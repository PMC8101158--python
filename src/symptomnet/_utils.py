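"""Shared numerical helpers."""
from __future__ import annotations

import numpy as np


def child_seed(seed: int | None, stream: str) -> int:
    """Derive a reproducible per-stage seed (< 2**31) from a global seed and a label."""
    if seed is None:
        return np.random.SeedSequence().generate_state(1)[0] % (2**31)
    ss = np.random.SeedSequence(int(seed) % (2**31), spawn_key=(abs(hash(stream)) % (2**31),))
    return int(ss.generate_state(1)[0] % (2**31))


def nearest_psd(mat: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Project a symmetric matrix onto the PSD cone by eigenvalue clipping.

    Keeps the unit diagonal by rescaling afterwards, which is adequate for the
    tie-induced near-PSD violations Spearman matrices exhibit.
    """
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    if vals.min() >= eps:
        return sym
    vals = np.clip(vals, max(eps, 1e-10), None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def is_symmetric(mat: np.ndarray, tol: float = 1e-10) -> bool:
    return mat.ndim == 2 and mat.shape[0] == mat.shape[1] and np.allclose(mat, mat.T, atol=tol)


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial correlation matrix rho_ij = -k_ij / sqrt(k_ii k_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    return rho
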