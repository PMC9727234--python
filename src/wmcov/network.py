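"""Weighted networks from significant positive edges, node strength, and
strength-score correlation with BH-FDR across regions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityMatrix

__all__ = [
    "WeightedNetwork",
    "NodeStrengthVector",
    "threshold_positive",
    "node_strength",
    "strength_score_correlation",
    "pearson_edge_pvalue",
]


@dataclass
class WeightedNetwork:
    weights: np.ndarray
    retained_mask: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        m = np.asarray(self.retained_mask, dtype=bool)
        if w.shape != m.shape or w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights/retained_mask must be matching square matrices")
        if np.abs(w - w.T).max() > 1e-12 or (m != m.T).any():
            raise ValueError("network must be symmetric")
        if np.diag(w).any() or np.diag(m).any():
            raise ValueError("network diagonal must be zero")
        if (w[m] <= 0).any():
            raise ValueError("retained edges must have positive weight")
        if w[~m].any():
            raise ValueError("removed edges must be zero")
        self.weights, self.retained_mask = w, m

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class NodeStrengthVector:
    strengths: np.ndarray
    region_ids: list[int]

    def __post_init__(self) -> None:
        s = np.asarray(self.strengths, dtype=np.float64)
        if s.ndim != 1 or len(s) != len(self.region_ids):
            raise ValueError("strengths/region_ids length mismatch")
        if (s < 0).any():
            raise ValueError("node strengths must be nonnegative")
        self.strengths = s


def pearson_edge_pvalue(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p-value for Pearson r via the t-distribution with ``df``."""
    r = np.clip(np.asarray(r, dtype=np.float64), -1.0, 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df)


def threshold_positive(conn: ConnectivityMatrix, alpha: float = 0.05) -> WeightedNetwork:
    """Keep edges with r > 0 and two-sided p < alpha (df = samples - 2)."""
    if conn.metric != "wavelet_pearson":
        raise ValueError(
            f"significance thresholding requires a Pearson-metric matrix, "
            f"got {conn.metric!r}"
        )
    if conn.n_samples_per_entry is None:
        raise ValueError("connectivity matrix lacks n_samples_per_entry")
    if conn.n_samples_per_entry < 4:
        raise ValueError("need at least 4 samples per correlation for a t-test")
    df = conn.n_samples_per_entry - 2
    vals = conn.values.copy()
    np.fill_diagonal(vals, 0.0)
    p = pearson_edge_pvalue(vals, df)
    keep = (vals > 0) & (p < alpha)
    np.fill_diagonal(keep, False)
    weights = np.where(keep, vals, 0.0)
    return WeightedNetwork(weights=weights, retained_mask=keep, alpha=alpha)


def node_strength(network: WeightedNetwork) -> NodeStrengthVector:
    """Sum of retained edge weights incident to each region."""
    return NodeStrengthVector(
        strengths=network.weights.sum(axis=1),
        region_ids=list(range(1, network.n_regions + 1)),
    )


def strength_score_correlation(
    strength_table: np.ndarray | pd.DataFrame,
    scores: np.ndarray | pd.Series,
    alpha: float = 0.05,
    fdr: bool = True,
) -> pd.DataFrame:
    """Correlate per-region node strengths with a cognitive score across subjects.

    ``strength_table`` is N subjects x R regions. Subjects with a missing
    score are dropped (complete-case); fewer than 10 complete cases is an
    error. Returns a DataFrame with columns region, r, p_raw, p_fdr,
    significant — p_fdr is Benjamini-Hochberg across the R regions.
    """
    if isinstance(strength_table, pd.DataFrame):
        region_names = list(strength_table.columns)
        S = strength_table.to_numpy(dtype=np.float64)
    else:
        S = np.asarray(strength_table, dtype=np.float64)
        region_names = list(range(1, S.shape[1] + 1))
    y = np.asarray(scores, dtype=np.float64)
    if len(y) != S.shape[0]:
        raise ValueError("scores length must match strength table rows")
    ok = np.isfinite(y)
    if ok.sum() < 10:
        raise ValueError(
            f"only {int(ok.sum())} complete cases (< 10); cannot correlate"
        )
    S, y = S[ok], y[ok]
    n = len(y)
    rs = np.empty(S.shape[1])
    ps = np.empty(S.shape[1])
    for k in range(S.shape[1]):
        col = S[:, k]
        if col.std() == 0 or y.std() == 0:
            rs[k], ps[k] = 0.0, 1.0
        else:
            rs[k], ps[k] = stats.pearsonr(col, y)
    if fdr:
        reject, p_adj, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    else:
        p_adj = ps.copy()
        reject = ps < alpha
    return pd.DataFrame(
        {
            "region": region_names,
            "r": rs,
            "p_raw": ps,
            "p_fdr": p_adj,
            "significant": reject,
        }
    )
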