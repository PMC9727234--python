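"""Brain-behaviour prediction protocol.

Per training fold: edges significantly correlated with the training scores
(two-sided p < alpha) are selected, features and target are standardized with
training statistics, and an epsilon-SVR with a radial-basis kernel at fixed
default hyperparameters (cost 1.0, epsilon 0.1, gamma = 1 / n_selected) is
fitted; the held-out fold is predicted on the original score scale. Repeated
k-fold cross-validation re-partitions subjects independently every repeat and
summarises pooled out-of-fold performance as mean +/- sd of r and MAE, with a
two-sided permutation p-value on the first repeat's predictions.

Also provided: split-half transfer between age groups, FDR-corrected
edge-score predictive patterns, and Cohen's d between per-repeat performance
samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from .connectivity import EdgeVector

__all__ = [
    "PredictionConfig",
    "PerformanceSummary",
    "PatternMatrix",
    "select_features",
    "fit_predict_svr",
    "repeated_cv",
    "permutation_pvalue",
    "split_half_transfer",
    "predictive_pattern",
    "cohens_d",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictionConfig:
    """Protocol parameters; defaults mirror the reference analysis."""

    k_folds: int = 10
    n_repeats: int = 1000
    selection_alpha: float = 0.05
    svr_cost: float = 1.0
    svr_epsilon: float = 0.1
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0 < self.selection_alpha < 1:
            raise ValueError("selection_alpha must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def as_dict(self) -> dict:
        return {
            "k_folds": self.k_folds,
            "n_repeats": self.n_repeats,
            "selection_alpha": self.selection_alpha,
            "svr": {
                "kernel": "rbf",
                "cost": self.svr_cost,
                "epsilon": self.svr_epsilon,
                "gamma": "1/n_selected_features",
                "standardize": "training-fold mean/sd on X and y",
            },
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass
class PerformanceSummary:
    r_mean: float
    r_sd: float
    mae_mean: float
    mae_sd: float
    permutation_p: float
    n_subjects_used: int
    per_repeat_r: np.ndarray = field(default_factory=lambda: np.array([]))
    per_repeat_mae: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        if not -1.0 <= self.r_mean <= 1.0:
            raise ValueError("r_mean must lie in [-1, 1]")
        if self.mae_mean < 0:
            raise ValueError("MAE must be nonnegative")
        if not 0.0 < self.permutation_p <= 1.0:
            raise ValueError("permutation p must lie in (0, 1]")

    def as_row(self) -> dict:
        return {
            "r_mean": self.r_mean,
            "r_sd": self.r_sd,
            "p": self.permutation_p,
            "mae_mean": self.mae_mean,
            "mae_sd": self.mae_sd,
            "n": self.n_subjects_used,
        }


@dataclass
class PatternMatrix:
    """Signed FDR-significance of edgewise score correlations, matrix form."""

    signs: np.ndarray
    r_values: np.ndarray
    p_fdr: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.signs)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("pattern matrix must be square")
        if (s != s.T).any() or np.diag(s).any():
            raise ValueError("pattern matrix must be symmetric with zero diagonal")
        if not np.isin(s, (-1, 0, 1)).all():
            raise ValueError("pattern entries must be -1, 0 or +1")


def _corr_with_pvalues(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise Pearson r and two-sided p of X against y.

    Constant columns get r = 0, p = 1 (excluded from selection by construction).
    """
    n = len(y)
    yc = y - y.mean()
    ysd = yc.std()
    Xc = X - X.mean(axis=0)
    xsd = Xc.std(axis=0)
    ok = (xsd > 0) & (ysd > 0)
    r = np.zeros(X.shape[1])
    if ok.any():
        r[ok] = (Xc[:, ok] * yc[:, None]).mean(axis=0) / (xsd[ok] * ysd)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    p = np.where(ok, 2.0 * stats.t.sf(np.abs(t), df), 1.0)
    return r, p


def select_features(
    edge_matrix: np.ndarray, scores: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Indices of edges whose correlation with the scores has p < alpha."""
    X = np.asarray(edge_matrix, dtype=np.float64)
    y = np.asarray(scores, dtype=np.float64)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("edge_matrix must be n_train x E matching scores")
    if X.shape[0] < 10:
        raise ValueError(f"need >= 10 training subjects, got {X.shape[0]}")
    n_const = int((X.std(axis=0) == 0).sum())
    if n_const:
        logger.warning("excluding %d constant edge column(s) from selection", n_const)
    _, p = _corr_with_pvalues(X, y)
    return np.flatnonzero(p < alpha)


def fit_predict_svr(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: PredictionConfig | None = None,
) -> np.ndarray:
    """Standardize with training statistics, fit epsilon-SVR, predict test.

    With zero feature columns (empty selection) the training mean is
    predicted for every test subject, and the event is logged.
    """
    config = config or PredictionConfig()
    X_train = np.asarray(X_train, dtype=np.float64)
    X_test = np.asarray(X_test, dtype=np.float64)
    y_train = np.asarray(y_train, dtype=np.float64)
    if X_train.ndim != 2 or X_test.ndim != 2:
        raise ValueError("feature matrices must be 2D")
    if not (
        np.isfinite(X_train).all()
        and np.isfinite(X_test).all()
        and np.isfinite(y_train).all()
    ):
        raise ValueError("inputs contain missing/non-finite values")
    if X_train.shape[1] == 0:
        logger.info("empty feature selection: predicting the training mean")
        return np.full(X_test.shape[0], y_train.mean())
    y_mu, y_sd = y_train.mean(), y_train.std()
    if y_sd == 0:
        return np.full(X_test.shape[0], y_mu)
    x_mu = X_train.mean(axis=0)
    x_sd = X_train.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    model = SVR(
        kernel="rbf",
        C=config.svr_cost,
        epsilon=config.svr_epsilon,
        gamma=1.0 / X_train.shape[1],
    )
    model.fit((X_train - x_mu) / x_sd, (y_train - y_mu) / y_sd)
    z = model.predict((X_test - x_mu) / x_sd)
    return z * y_sd + y_mu


def permutation_pvalue(
    observed: np.ndarray,
    predicted: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided permutation p for corr(observed, predicted).

    ``p = (1 + #{|r_perm| >= |r_obs|}) / (n_permutations + 1)``, shuffling the
    observed scores.
    """
    obs = np.asarray(observed, dtype=np.float64)
    pred = np.asarray(predicted, dtype=np.float64)
    if len(obs) != len(pred) or len(obs) < 10:
        raise ValueError("need two equal-length vectors of >= 10 values")
    if obs.std() == 0 or pred.std() == 0:
        raise ValueError("constant vector: correlation undefined")
    r_obs = abs(np.corrcoef(obs, pred)[0, 1])
    rng = np.random.default_rng(seed)
    pred_c = (pred - pred.mean()) / (pred.std() * len(pred))
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(obs)
        r = abs(np.dot(pred_c, (perm - perm.mean()) / perm.std()))
        if r >= r_obs - 1e-15:
            count += 1
    return (1 + count) / (n_permutations + 1)


def _kfold_indices(
    n: int, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [fold for fold in np.array_split(order, k)]


def _one_repeat(
    X: np.ndarray,
    y: np.ndarray,
    config: PredictionConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One repeat of k-fold CV; returns pooled out-of-fold predictions."""
    n = len(y)
    pred = np.empty(n)
    for test_idx in _kfold_indices(n, config.k_folds, rng):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        sel = select_features(X[train_idx], y[train_idx], config.selection_alpha)
        pred[test_idx] = fit_predict_svr(
            X[np.ix_(train_idx, sel)], y[train_idx], X[np.ix_(test_idx, sel)], config
        )
    return pred


def repeated_cv(
    edge_table: np.ndarray,
    scores: np.ndarray,
    config: PredictionConfig | None = None,
) -> PerformanceSummary:
    """Repeated k-fold CV with in-fold feature selection.

    Subjects with missing scores are dropped first (complete-case). Per
    repeat, r and MAE are computed on the pooled out-of-fold predictions; the
    permutation p-value uses the first repeat's predictions.
    """
    config = config or PredictionConfig()
    X = np.asarray(edge_table, dtype=np.float64)
    y = np.asarray(scores, dtype=np.float64)
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    n = len(y)
    if n < 30:
        raise ValueError(f"need >= 30 complete cases, got {n}")
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_repeats + 1)
    rs = np.empty(config.n_repeats)
    maes = np.empty(config.n_repeats)
    first_pred: np.ndarray | None = None
    for rep in range(config.n_repeats):
        rng = np.random.default_rng(seeds[rep])
        pred = _one_repeat(X, y, config, rng)
        if pred.std() == 0:
            rs[rep] = 0.0
        else:
            rs[rep] = np.corrcoef(y, pred)[0, 1]
        maes[rep] = np.abs(pred - y).mean()
        if rep == 0:
            first_pred = pred
    if first_pred is None or first_pred.std() == 0:
        perm_p = 1.0
    else:
        perm_seed = int(np.random.default_rng(seeds[-1]).integers(2**31))
        perm_p = permutation_pvalue(y, first_pred, config.n_permutations, perm_seed)
    return PerformanceSummary(
        r_mean=float(rs.mean()),
        r_sd=float(rs.std(ddof=1)) if config.n_repeats > 1 else 0.0,
        mae_mean=float(maes.mean()),
        mae_sd=float(maes.std(ddof=1)) if config.n_repeats > 1 else 0.0,
        permutation_p=perm_p,
        n_subjects_used=n,
        per_repeat_r=rs,
        per_repeat_mae=maes,
    )


def _transfer(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    config: PredictionConfig,
    perm_seed: int,
) -> PerformanceSummary:
    sel = select_features(X_tr, y_tr, config.selection_alpha)
    pred = fit_predict_svr(X_tr[:, sel], y_tr, X_te[:, sel], config)
    r = float(np.corrcoef(y_te, pred)[0, 1]) if pred.std() > 0 else 0.0
    mae = float(np.abs(pred - y_te).mean())
    if pred.std() > 0:
        p = permutation_pvalue(y_te, pred, config.n_permutations, perm_seed)
    else:
        p = 1.0
    return PerformanceSummary(
        r_mean=r,
        r_sd=0.0,
        mae_mean=mae,
        mae_sd=0.0,
        permutation_p=p,
        n_subjects_used=len(y_te),
        per_repeat_r=np.array([r]),
        per_repeat_mae=np.array([mae]),
    )


def split_half_transfer(
    edge_table: np.ndarray,
    scores: np.ndarray,
    ages: np.ndarray,
    config: PredictionConfig | None = None,
) -> tuple[PerformanceSummary, PerformanceSummary]:
    """Train on one age half, test on the other, in both directions.

    The split is at the mean age of the complete cases; subjects exactly at
    the mean go to the younger group. Returns (young-to-old, old-to-young).
    """
    config = config or PredictionConfig()
    X = np.asarray(edge_table, dtype=np.float64)
    y = np.asarray(scores, dtype=np.float64)
    a = np.asarray(ages, dtype=np.float64)
    ok = np.isfinite(y)
    X, y, a = X[ok], y[ok], a[ok]
    young = a <= a.mean()
    old = ~young
    if young.sum() < 15 or old.sum() < 15:
        raise ValueError(
            f"each age group needs >= 15 complete cases "
            f"(young={int(young.sum())}, old={int(old.sum())})"
        )
    s1, s2 = np.random.SeedSequence(config.seed).spawn(2)
    y2o = _transfer(
        X[young], y[young], X[old], y[old], config,
        int(np.random.default_rng(s1).integers(2**31)),
    )
    o2y = _transfer(
        X[old], y[old], X[young], y[young], config,
        int(np.random.default_rng(s2).integers(2**31)),
    )
    return y2o, o2y


def predictive_pattern(
    edge_table: np.ndarray,
    scores: np.ndarray,
    alpha: float = 0.05,
    edge_index: list[tuple[int, int]] | None = None,
    n_regions: int | None = None,
) -> PatternMatrix:
    """Edgewise score correlations, BH-FDR over edges, signed matrix form."""
    X = np.asarray(edge_table, dtype=np.float64)
    y = np.asarray(scores, dtype=np.float64)
    ok = np.isfinite(y)
    X, y = X[ok], y[ok]
    if len(y) < 30:
        raise ValueError(f"need >= 30 complete cases, got {len(y)}")
    r, p = _corr_with_pvalues(X, y)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    E = X.shape[1]
    if edge_index is None:
        if n_regions is None:
            n_regions = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
        iu = np.triu_indices(n_regions, k=1)
        edge_index = list(zip((iu[0] + 1).tolist(), (iu[1] + 1).tolist()))
    if len(edge_index) != E:
        raise ValueError("edge_index length does not match edge table width")
    R = max(j for _, j in edge_index)
    signs = np.zeros((R, R), dtype=np.int64)
    r_mat = np.zeros((R, R))
    p_mat = np.ones((R, R))
    for k, (i, j) in enumerate(edge_index):
        s = int(np.sign(r[k])) if reject[k] else 0
        signs[i - 1, j - 1] = signs[j - 1, i - 1] = s
        r_mat[i - 1, j - 1] = r_mat[j - 1, i - 1] = r[k]
        p_mat[i - 1, j - 1] = p_mat[j - 1, i - 1] = p_adj[k]
    np.fill_diagonal(p_mat, 0.0)
    return PatternMatrix(signs=signs, r_values=r_mat, p_fdr=p_mat)


def cohens_d(perf_a: np.ndarray, perf_b: np.ndarray) -> float:
    """Standardized mean difference with pooled (ddof=1) standard deviation."""
    a = np.asarray(perf_a, dtype=np.float64)
    b = np.asarray(perf_b, dtype=np.float64)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled standard deviation with unequal means")
    return float((a.mean() - b.mean()) / pooled)


def edge_table_from_vectors(edge_vectors: list[EdgeVector]) -> np.ndarray:
    """Stack per-subject edge vectors into an N x E table (index-checked)."""
    if not edge_vectors:
        raise ValueError("no edge vectors supplied")
    index = edge_vectors[0].edge_index
    for ev in edge_vectors[1:]:
        if ev.edge_index != index:
            raise ValueError("edge vectors have inconsistent edge indices")
    return np.stack([ev.values for ev in edge_vectors])
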