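"""Item screening, topological-overlap reduction and the Spearman matrix.

Before network estimation, ordinal symptom items are screened for near-zero
variance and heavy skew, and near-duplicate item pairs (e.g. loss of pleasure
with loss of interest) are detected by comparing their correlation profiles
against every third item.  Detected pairs are merged into a single variable by
principal component analysis and rescaled back to the Likert range, and the
association structure is summarised by a Spearman rank-correlation matrix.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._utils import nearest_psd
from .synthetic import SymptomCohort


@dataclass
class ScreenReport:
    item_names: list[str]
    near_zero_variance: np.ndarray
    skewness: np.ndarray
    skew_flag: np.ndarray
    variance: np.ndarray
    variance_ratio: np.ndarray  # item variance / cohort median variance
    flagged: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class OverlapResult:
    """Candidate redundant pairs and the evidence behind each decision."""

    pairs: list[tuple[int, int]]
    correlations: dict[tuple[int, int], float]
    fraction_different: dict[tuple[int, int], float]
    decisions: dict[tuple[int, int], str]  # "merge" | "keep"
    min_cor: float
    threshold: float
    alpha: float

    @property
    def merge_candidates(self) -> list[tuple[int, int]]:
        return [p for p in self.pairs if self.decisions[p] == "merge"]


def screen_items(cohort: SymptomCohort, freq_ratio: float = 19.0,
                 max_unique: int = 2, skew_threshold: float = 2.0) -> ScreenReport:
    """Flag items with near-zero variance or heavy asymmetry.

    Near-zero variance uses the frequency-ratio heuristic: the ratio of the
    most- to second-most-common value exceeds ``freq_ratio`` and the item takes
    at most ``max_unique`` distinct values (a constant item always flags).
    Skewness beyond ``skew_threshold`` in absolute value is reported but, as in
    rank-based pipelines, is advisory only.  Removal is the caller's decision.
    """
    X = cohort.items
    if X.shape[0] < 2:
        raise ValueError("screening requires at least 2 subjects")
    p = X.shape[1]
    nzv = np.zeros(p, dtype=bool)
    skews = np.zeros(p)
    var = X.var(axis=0, ddof=1)
    med_var = np.median(var) if np.median(var) > 0 else np.nan
    flagged: list[tuple[str, str]] = []
    for k in range(p):
        vals, counts = np.unique(X[:, k], return_counts=True)
        if len(vals) == 1:
            nzv[k] = True
        elif len(vals) <= max_unique:
            order = np.sort(counts)[::-1]
            if order[0] / order[1] > freq_ratio:
                nzv[k] = True
        skews[k] = stats.skew(X[:, k], bias=False) if len(vals) > 1 else 0.0
        if nzv[k]:
            flagged.append((cohort.item_names[k], "near-zero variance"))
        if abs(skews[k]) > skew_threshold:
            flagged.append((cohort.item_names[k], f"skewness {skews[k]:.2f}"))
    return ScreenReport(
        item_names=list(cohort.item_names),
        near_zero_variance=nzv,
        skewness=skews,
        skew_flag=np.abs(skews) > skew_threshold,
        variance=var,
        variance_ratio=var / med_var,
        flagged=flagged,
    )


def dependent_correlation_test(r_jk: float, r_hk: float, r_jh: float, n: int) -> tuple[float, float]:
    """Two-sided test of H0: rho_jk = rho_hk for overlapping dependent
    correlations (back-transformed-average z statistic, Hittner et al. 2003).

    ``j`` and ``h`` are the candidate pair, ``k`` the shared third variable.
    Returns ``(z, p)``.
    """
    if n < 4:
        raise ValueError("need n >= 4 for the dependent-correlation test")
    clip = lambda r: np.clip(r, -0.999999, 0.999999)
    z_jk = np.arctanh(clip(r_jk))
    z_hk = np.arctanh(clip(r_hk))
    if z_jk == z_hk:
        return 0.0, 1.0
    rbar = np.tanh((z_jk + z_hk) / 2.0)
    r2 = rbar * rbar
    num = r_jh * (1.0 - 2.0 * r2) - 0.5 * r2 * (1.0 - 2.0 * r2 - r_jh * r_jh)
    c = np.clip(num / ((1.0 - r2) ** 2), -0.999999, 0.999999)
    z = (z_jk - z_hk) * np.sqrt((n - 3.0) / (2.0 - 2.0 * c))
    pval = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(pval)


def find_overlap(items: np.ndarray, item_names: list[str] | None = None,
                 min_cor: float = 0.5, threshold: float = 0.25,
                 alpha: float = 0.05) -> OverlapResult:
    """Detect topologically overlapping (near-redundant) item pairs.

    Every pair with Spearman correlation >= ``min_cor`` is tested: for each
    third item k, H0: cor(i,k) = cor(j,k) via the dependent-correlation test.
    A pair whose correlation profiles differ significantly for fewer than
    ``threshold`` of the third items is a merge candidate.
    """
    items = np.asarray(items, dtype=float)
    n, p = items.shape
    result = OverlapResult(pairs=[], correlations={}, fraction_different={},
                           decisions={}, min_cor=min_cor, threshold=threshold, alpha=alpha)
    if p < 3:
        warnings.warn("fewer than 3 items: overlap detection skipped", stacklevel=2)
        return result
    if n < 20:
        raise ValueError("need n >= 20 subjects for the dependent-correlation test")
    R = spearman_matrix(items, [str(k) for k in range(p)], project_psd=False)
    for i in range(p):
        for j in range(i + 1, p):
            if R[i, j] < min_cor:
                continue
            others = [k for k in range(p) if k not in (i, j)]
            n_sig = 0
            for k in others:
                _, pval = dependent_correlation_test(R[i, k], R[j, k], R[i, j], n)
                if pval < alpha:
                    n_sig += 1
            frac = n_sig / len(others)
            pair = (i, j)
            result.pairs.append(pair)
            result.correlations[pair] = float(R[i, j])
            result.fraction_different[pair] = frac
            result.decisions[pair] = "merge" if frac < threshold else "keep"
    return result


def merge_pair(cohort: SymptomCohort, pair: tuple[int, int]) -> SymptomCohort:
    """Merge a redundant item pair into one variable via PCA.

    The first principal component of the standardized pair is oriented to
    correlate positively with the pair mean and min-max rescaled to the
    original Likert range (the wider range if they differ, with a warning).
    The merged item is named "a/b" and replaces both parents.
    """
    i, j = pair
    X = cohort.items
    xi, xj = X[:, i], X[:, j]
    Z = np.column_stack([xi, xj])
    sd = Z.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("cannot merge a constant item")
    Zs = (Z - Z.mean(0)) / sd
    # PC1 of a standardized pair is the (normalized) sum or difference axis.
    _, _, vt = np.linalg.svd(Zs, full_matrices=False)
    pc1 = Zs @ vt[0]
    if np.corrcoef(pc1, Z.mean(axis=1))[0, 1] < 0:
        pc1 = -pc1
    lo_i, hi_i = cohort.item_ranges[i]
    lo_j, hi_j = cohort.item_ranges[j]
    if (lo_i, hi_i) != (lo_j, hi_j):
        warnings.warn(
            f"merging items with different Likert ranges; rescaling to the wider",
            stacklevel=2,
        )
    lo, hi = min(lo_i, lo_j), max(hi_i, hi_j)
    span = pc1.max() - pc1.min()
    merged = np.full_like(pc1, (lo + hi) / 2.0) if span == 0 else \
        lo + (pc1 - pc1.min()) / span * (hi - lo)

    keep = [k for k in range(cohort.n_items) if k not in (i, j)]
    new_items = np.column_stack([X[:, keep], merged])
    new_names = [cohort.item_names[k] for k in keep] + [
        f"{cohort.item_names[i]}/{cohort.item_names[j]}"
    ]
    new_ranges = [cohort.item_ranges[k] for k in keep] + [(lo, hi)]
    return SymptomCohort(
        items=new_items,
        item_names=new_names,
        item_ranges=new_ranges,
        covariates=cohort.covariates,
        outcome=cohort.outcome,
        group=cohort.group,
        study=cohort.study,
        covariate_names=list(cohort.covariate_names),
    )


def spearman_matrix(items: np.ndarray, item_names: list[str] | None = None,
                    project_psd: bool = True) -> np.ndarray:
    """Spearman rank-correlation matrix (average ranks for ties).

    Constant columns make the rank correlation undefined and are rejected.
    If tie-induced rounding pushes the matrix slightly outside the PSD cone
    (beyond -1e-8), it is projected to the nearest PSD correlation matrix.
    """
    items = np.asarray(items, dtype=float)
    n, p = items.shape
    if np.isnan(items).any():
        raise ValueError("missing values are not supported")
    sd = items.std(axis=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        names = [item_names[b] if item_names else str(b) for b in bad]
        raise ValueError(f"constant column(s) make Spearman undefined: {names}")
    ranks = np.apply_along_axis(stats.rankdata, 0, items)
    R = np.corrcoef(ranks, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    if project_psd and np.linalg.eigvalsh(R).min() < -1e-8:
        warnings.warn("Spearman matrix not PSD; projecting", stacklevel=2)
        R = nearest_psd(R)
    return R


def reduce_cohort(cohort: SymptomCohort, min_cor: float = 0.5,
                  threshold: float = 0.25, alpha: float = 0.05) -> tuple[SymptomCohort, OverlapResult]:
    """Full redundancy-reduction pass: detect overlap, merge all candidate
    pairs greedily (strongest correlation first, each item merged once)."""
    res = find_overlap(cohort.items, cohort.item_names, min_cor, threshold, alpha)
    used: set[int] = set()
    chosen: list[tuple[int, int]] = []
    for pair in sorted(res.merge_candidates, key=lambda p: -res.correlations[p]):
        if used.isdisjoint(pair):
            chosen.append(pair)
            used.update(pair)
    out = cohort
    # merge by current index: recompute positions after each merge
    names = list(cohort.item_names)
    for i, j in chosen:
        ni, nj = cohort.item_names[i], cohort.item_names[j]
        ci, cj = out.item_names.index(ni), out.item_names.index(nj)
        out = merge_pair(out, (min(ci, cj), max(ci, cj)))
    return out, res
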