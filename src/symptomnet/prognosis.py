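"""Item-level prognosis modelling.

Does knowing the individual symptom profile predict the follow-up outcome
better than conventional scale totals?  The item severities (plus duration
covariates) enter an elastic-net regression tuned by repeated k-fold
cross-validation over a (mixing, penalty) grid; the comparator is an ordinary
least-squares model on the depression and anxiety sum scores evaluated on the
*identical* CV partitions.  Item importance for the fitted elastic net is
estimated by Monte-Carlo (permutation-sampling) Shapley values, which remain
meaningful when predictors are correlated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, LinearRegression
from sklearn.model_selection import RepeatedKFold

from .synthetic import SymptomCohort


@dataclass
class ENRConfig:
    alpha_grid: np.ndarray = field(default_factory=lambda: np.arange(0.1, 1.01, 0.1))
    lambda_grid: np.ndarray | None = None  # auto log-spaced path per alpha
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    repeats: int = 10
    folds: int = 10
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.alpha_grid.size == 0:
            raise ValueError("alpha_grid must be non-empty")


@dataclass
class CVPerformance:
    rmse: float
    mae: float
    r2: float
    fold_rmse: np.ndarray
    fold_mae: np.ndarray
    fold_r2: np.ndarray
    oof_predictions: np.ndarray  # (repeats, n) out-of-fold predictions


@dataclass
class FittedModel:
    coef: np.ndarray  # original-scale slopes
    intercept: float
    feature_names: list[str]
    alpha: float | None = None  # elastic-net mixing
    lam: float | None = None    # penalty strength (standardized scale)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef + self.intercept


@dataclass
class PrognosisReport:
    item_model: FittedModel
    item_cv: CVPerformance
    sum_model: FittedModel
    sum_cv: CVPerformance
    partition_key: tuple
    shapley_mean_abs: np.ndarray | None = None
    shapley_mean_signed: np.ndarray | None = None
    shapley_rank: np.ndarray | None = None
    shapley_mc_reps: int = 0


def cv_partitions(n: int, folds: int, repeats: int, seed: int):
    """Deterministic repeated k-fold split indices, a function of
    (n, folds, repeats, seed) only — shared by both models."""
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    return list(rkf.split(np.arange(n)))


def evaluate(predictions: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """RMSE, MAE and R^2 (SST about the mean of y in the evaluation set).

    Held-out R^2 may be negative.
    """
    predictions = np.asarray(predictions, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ValueError("cannot evaluate on an empty set")
    if predictions.shape != y.shape:
        raise ValueError("length mismatch")
    err = y - predictions
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mae = float(np.mean(np.abs(err)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err ** 2)) / sst if sst > 0 else np.nan
    return rmse, mae, r2


def _lambda_path(Xs: np.ndarray, y: np.ndarray, alpha: float, config: ENRConfig) -> np.ndarray:
    if config.lambda_grid is not None:
        return np.asarray(config.lambda_grid, dtype=float)
    n = len(y)
    yc = y - y.mean()
    lam_max = np.abs(Xs.T @ yc).max() / (n * max(alpha, 0.01))
    return np.logspace(np.log10(lam_max), np.log10(lam_max * config.lambda_min_ratio),
                       config.n_lambda)


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd, mu, sd


def _fit_enet_path(Xs, y, alpha, lams):
    """Elastic-net coefficient path with warm starts, largest penalty first."""
    model = ElasticNet(l1_ratio=alpha, warm_start=True, max_iter=5000, tol=1e-5)
    coefs, intercepts = [], []
    for lam in lams:
        model.set_params(alpha=lam)
        model.fit(Xs, y)
        coefs.append(model.coef_.copy())
        intercepts.append(model.intercept_)
    return np.asarray(coefs), np.asarray(intercepts)


def fit_enr(X: np.ndarray, y: np.ndarray, config: ENRConfig | None = None,
            feature_names: list[str] | None = None) -> tuple[FittedModel, CVPerformance, dict]:
    """Elastic-net regression with repeated k-fold CV over a (alpha, lambda) grid.

    Predictors are standardized inside each training fold; the (alpha, lambda)
    pair minimizing the mean out-of-fold squared error across all
    repeats x folds is selected, the model refit on all data, and out-of-fold
    RMSE/MAE/R^2 at the optimum reported (metrics per repeat, averaged).
    Constant/singular predictors are kept — the penalty handles them.
    """
    config = config or ENRConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= config.folds:
        raise ValueError("need n > folds")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not supported")
    feature_names = feature_names or [f"x{j}" for j in range(p)]

    Xs_all, _, _ = _standardize(X)
    lam_grids = {a: _lambda_path(Xs_all, y, a, config) for a in config.alpha_grid}
    splits = cv_partitions(n, config.folds, config.repeats, config.seed)

    # Pass 1: accumulate out-of-fold SSE over the whole grid (no predictions
    # stored); pass 2 recomputes out-of-fold predictions at the optimum only.
    n_lam = len(next(iter(lam_grids.values())))
    sse = {a: np.zeros(n_lam) for a in config.alpha_grid}
    for tr, te in splits:
        Xtr, mu, sd = _standardize(X[tr]) if config.standardize else (X[tr], 0.0, 1.0)
        Xte = (X[te] - mu) / sd if config.standardize else X[te]
        for a in config.alpha_grid:
            coefs, icpts = _fit_enet_path(Xtr, y[tr], a, lam_grids[a])
            preds = Xte @ coefs.T + icpts[None, :]
            sse[a] += ((preds - y[te][:, None]) ** 2).sum(axis=0)
    best_a, best_l_idx, best_err = None, None, np.inf
    for a in config.alpha_grid:
        idx = int(np.argmin(sse[a]))
        if sse[a][idx] < best_err:
            best_a, best_l_idx, best_err = a, idx, sse[a][idx]
    best_lam = float(lam_grids[best_a][best_l_idx])

    oof_flat = np.zeros((len(splits), n))
    warm_path = lam_grids[best_a][:best_l_idx + 1]
    for s_idx, (tr, te) in enumerate(splits):
        Xtr, mu, sd = _standardize(X[tr]) if config.standardize else (X[tr], 0.0, 1.0)
        Xte = (X[te] - mu) / sd if config.standardize else X[te]
        coefs, icpts = _fit_enet_path(Xtr, y[tr], best_a, warm_path)
        oof_flat[s_idx, te] = Xte @ coefs[-1] + icpts[-1]
    cv = _collect_cv(oof_flat, y, splits, config)
    Xs, mu, sd = _standardize(X) if config.standardize else (X, np.zeros(p), np.ones(p))
    final = ElasticNet(l1_ratio=best_a, alpha=best_lam, max_iter=20000, tol=1e-7)
    final.fit(Xs, y)
    coef_orig = final.coef_ / sd if config.standardize else final.coef_
    icpt = float(y.mean() - coef_orig @ mu) if config.standardize else float(final.intercept_)
    model = FittedModel(coef=coef_orig, intercept=icpt, feature_names=feature_names,
                        alpha=float(best_a), lam=best_lam)
    extras = {"cv_mse": {float(a): sse[a] / (len(splits) * n / config.folds)
                         for a in config.alpha_grid},
              "lambda_grids": {float(a): lam_grids[a] for a in config.alpha_grid}}
    return model, cv, extras


def _collect_cv(oof_flat: np.ndarray, y: np.ndarray, splits, config: ENRConfig) -> CVPerformance:
    """Assemble per-repeat out-of-fold prediction vectors and fold metrics."""
    n = len(y)
    n_splits_per_rep = config.folds
    oof_by_rep = np.zeros((config.repeats, n))
    fold_rmse, fold_mae, fold_r2 = [], [], []
    for s_idx, (tr, te) in enumerate(splits):
        rep = s_idx // n_splits_per_rep
        oof_by_rep[rep, te] = oof_flat[s_idx, te]
        r, m, r2 = evaluate(oof_flat[s_idx, te], y[te])
        fold_rmse.append(r)
        fold_mae.append(m)
        fold_r2.append(r2)
    rep_metrics = np.array([evaluate(oof_by_rep[r], y) for r in range(config.repeats)])
    return CVPerformance(
        rmse=float(rep_metrics[:, 0].mean()),
        mae=float(rep_metrics[:, 1].mean()),
        r2=float(rep_metrics[:, 2].mean()),
        fold_rmse=np.asarray(fold_rmse),
        fold_mae=np.asarray(fold_mae),
        fold_r2=np.asarray(fold_r2),
        oof_predictions=oof_by_rep,
    )


def fit_sumscore(sums: np.ndarray, y: np.ndarray, config: ENRConfig | None = None,
                 feature_names: list[str] | None = None) -> tuple[FittedModel, CVPerformance]:
    """OLS on the scale totals, evaluated on the same CV partitions as fit_enr."""
    config = config or ENRConfig()
    sums = np.asarray(sums, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if sums.ndim == 1:
        sums = sums[:, None]
    if sums.shape[1] > 1:
        cc = np.corrcoef(sums, rowvar=False)
        if np.abs(cc[np.triu_indices_from(cc, 1)]).max() > 0.95:
            import warnings
            warnings.warn("sum-score totals are nearly collinear", stacklevel=2)
    splits = cv_partitions(n, config.folds, config.repeats, config.seed)
    oof_flat = np.zeros((len(splits), n))
    for s_idx, (tr, te) in enumerate(splits):
        lr = LinearRegression().fit(sums[tr], y[tr])
        oof_flat[s_idx, te] = lr.predict(sums[te])
    cv = _collect_cv(oof_flat, y, splits, config)
    lr = LinearRegression().fit(sums, y)
    names = feature_names or [f"total{j}" for j in range(sums.shape[1])]
    model = FittedModel(coef=lr.coef_, intercept=float(lr.intercept_), feature_names=names)
    return model, cv


def shapley_importance(model, X: np.ndarray, mc_reps: int = 500, seed: int = 0
                       ) -> dict:
    """Monte-Carlo Shapley values for every (subject, feature) pair.

    Sampling estimator: per repetition, draw one feature permutation and one
    background row per subject, then walk through the permutation replacing
    background values with the subject's own; the prediction increment when a
    feature is switched in is its marginal contribution.  Summing over
    features telescopes to f(x) - f(z), so the efficiency property holds per
    repetition up to background sampling noise.

    Returns per-pair means, Monte-Carlo standard errors, mean |value| and
    mean signed value per feature, and the importance ranking.
    """
    if mc_reps < 10:
        raise ValueError("mc_reps < 10 is too unstable")
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    mean = np.zeros((n, p))
    m2 = np.zeros((n, p))
    for rep in range(mc_reps):
        order = rng.permutation(p)
        Z = X[rng.integers(0, n, size=n)]
        current = Z.copy()
        f_prev = model.predict(current)
        contrib = np.zeros((n, p))
        for j in order:
            current[:, j] = X[:, j]
            f_new = model.predict(current)
            contrib[:, j] = f_new - f_prev
            f_prev = f_new
        delta = contrib - mean
        mean += delta / (rep + 1)
        m2 += delta * (contrib - mean)
    se = np.sqrt(m2 / (mc_reps * (mc_reps - 1)))
    mean_abs = np.abs(mean).mean(axis=0)
    mean_signed = mean.mean(axis=0)
    rank = np.argsort(-mean_abs)
    return {
        "values": mean,
        "se": se,
        "mean_abs": mean_abs,
        "mean_signed": mean_signed,
        "rank": rank,
        "mc_reps": mc_reps,
    }


def compare_models(report: PrognosisReport) -> dict:
    """Paired item-model vs sum-score-model comparison on identical partitions."""
    it, sm = report.item_cv, report.sum_cv
    if it.fold_rmse.shape != sm.fold_rmse.shape:
        raise ValueError("models were evaluated on different partitions")
    out = {}
    for metric in ("rmse", "mae", "r2"):
        fi = getattr(it, f"fold_{metric}")
        fs = getattr(sm, f"fold_{metric}")
        d = fi - fs
        out[metric] = {
            "items": getattr(it, metric),
            "sum_scores": getattr(sm, metric),
            "diff": getattr(it, metric) - getattr(sm, metric),
            "fold_diff_mean": float(d.mean()),
            "fold_diff_sd": float(d.std(ddof=1)),
        }
    return out


def sum_scores(cohort: SymptomCohort) -> tuple[np.ndarray, list[str]]:
    """Scale totals: the depression (0-3 Likert) items summed, and the
    anxiety-like (wider-range) items summed.  Falls back to one grand total
    when all items share a range."""
    ranges = np.array([hi for _, hi in cohort.item_ranges])
    dep = cohort.items[:, ranges == 3].sum(axis=1)
    anx = cohort.items[:, ranges != 3].sum(axis=1)
    if (ranges == 3).all() or (ranges != 3).all():
        return cohort.items.sum(axis=1)[:, None], ["total"]
    return np.column_stack([dep, anx]), ["dep_total", "anx_total"]


def prognosis_analysis(cohort: SymptomCohort, config: ENRConfig | None = None,
                       mc_reps: int = 500, include_covariates: bool = True,
                       run_shapley: bool = True) -> PrognosisReport:
    """Full item-vs-sum-score prognosis comparison on one cohort."""
    config = config or ENRConfig()
    X = cohort.items
    names = list(cohort.item_names)
    if include_covariates and cohort.covariates.size:
        X = np.column_stack([X, cohort.covariates])
        names = names + list(cohort.covariate_names)
    y = cohort.outcome
    item_model, item_cv, _ = fit_enr(X, y, config, feature_names=names)
    sums, sum_names = sum_scores(cohort)
    sum_model, sum_cv = fit_sumscore(sums, y, config, feature_names=sum_names)
    report = PrognosisReport(
        item_model=item_model, item_cv=item_cv,
        sum_model=sum_model, sum_cv=sum_cv,
        partition_key=(len(y), config.folds, config.repeats, config.seed),
    )
    if run_shapley:
        shap = shapley_importance(item_model, X, mc_reps=mc_reps, seed=config.seed)
        report.shapley_mean_abs = shap["mean_abs"]
        report.shapley_mean_signed = shap["mean_signed"]
        report.shapley_rank = shap["rank"]
        report.shapley_mc_reps = mc_reps
    return report
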