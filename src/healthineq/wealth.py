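"""Asset-based wealth index: weighted first-principal-component scoring.

The socioeconomic index follows the standard DHS construction: dichotomous
durable-asset indicators are standardised with survey-weighted means and
standard deviations, the first eigenvector of the weighted correlation
matrix supplies the factor loadings, and each individual's wealth score is
the projection of her standardised asset vector onto that eigenvector.
Because an eigenvector's sign is arbitrary, the score is oriented so it
correlates positively with the raw count of assets owned (more assets =
richer); when the raw eigenvector points the other way the flip is
recorded. Quintiles Q1 (poorest 20%) .. Q5 (richest 20%) are assigned by a
weighted cumulative walk along the score order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SurveyDataset

logger = logging.getLogger(__name__)

QUINTILE_LABELS = ("Q1", "Q2", "Q3", "Q4", "Q5")


@dataclass
class WealthIndexResult:
    score: np.ndarray
    loadings: pd.Series
    explained_variance_ratio: float
    orientation_flipped: bool
    quintile: pd.Categorical | None = None
    dropped_assets: list[str] = field(default_factory=list)


def _weighted_moments(x: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    W = w.sum()
    mean = (w[:, None] * x).sum(axis=0) / W
    var = (w[:, None] * (x - mean) ** 2).sum(axis=0) / W
    return mean, var


def pca_wealth_score(
    assets: pd.DataFrame | np.ndarray,
    weights: np.ndarray,
) -> WealthIndexResult:
    """First-PC wealth score of 0/1 asset indicators under survey weights.

    Standardisation and the correlation matrix both use the population
    (divide-by-total-weight) weighted convention, so results are invariant
    to rescaling all weights. Constant asset columns carry no information
    and are dropped with a warning; if every column is constant the asset
    matrix is degenerate and an error is raised.
    """
    if isinstance(assets, pd.DataFrame):
        names = list(assets.columns)
        X = assets.to_numpy(float)
    else:
        X = np.asarray(assets, float)
        names = [f"asset_{k}" for k in range(X.shape[1])]
    w = np.asarray(weights, float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 asset columns")
    if len(w) != X.shape[0]:
        raise ValueError("weights length must match number of rows")
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise ValueError("weights must be finite and strictly positive")

    mean, var = _weighted_moments(X, w)
    keep = var > 0
    dropped = [n for n, k in zip(names, keep) if not k]
    if dropped:
        logger.warning("pca_wealth_score: dropping constant asset columns %s", dropped)
    if not keep.any() or keep.sum() < 1:
        raise ValueError("degenerate asset matrix: all asset columns constant")
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    mean, var = mean[keep], var[keep]

    Z = (X - mean) / np.sqrt(var)
    W = w.sum()
    corr = (Z * w[:, None]).T @ Z / W
    evals, evecs = np.linalg.eigh(corr)
    v = evecs[:, -1]
    score = Z @ v

    raw_count = X.sum(axis=1)
    cov = np.sum(w * (score - np.average(score, weights=w))
                 * (raw_count - np.average(raw_count, weights=w))) / W
    flipped = cov < 0
    if flipped:
        score = -score
        v = -v
    evr = float(evals[-1] / evals.sum())
    return WealthIndexResult(
        score=score,
        loadings=pd.Series(v, index=names, name="loading"),
        explained_variance_ratio=evr,
        orientation_flipped=bool(flipped),
        dropped_assets=dropped,
    )


def assign_quintiles(
    score: np.ndarray, weights: np.ndarray, n_groups: int = 5
) -> pd.Categorical:
    """Weighted quintile labels Q1..Q5 along the score order.

    Individuals are sorted by (score, stable input order); each takes the
    group of its cumulative-weight midpoint (cut points at the weighted
    20/40/60/80 percentiles). Individuals with exactly tied scores form one
    block and all receive the label of the block's first member, so the
    label is a function of the score alone and monotone in it. Fewer than
    ``n_groups`` distinct scores triggers a mass-ties warning.
    """
    s = np.asarray(score, float)
    w = np.asarray(weights, float)
    if s.size == 0:
        raise ValueError("empty input")
    if np.any(~np.isfinite(s)):
        raise ValueError("scores must be finite")
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise ValueError("weights must be finite and strictly positive")
    labels = [f"Q{i + 1}" for i in range(n_groups)]
    if len(np.unique(s)) < n_groups:
        logger.warning(
            "assign_quintiles: only %d distinct scores for %d groups (mass ties)",
            len(np.unique(s)), n_groups,
        )
    order = np.argsort(s, kind="stable")
    ws = w[order]
    cum = np.cumsum(ws)
    W = cum[-1]
    mid = (cum - ws / 2.0) / W
    grp = np.minimum((mid * n_groups).astype(int), n_groups - 1)
    # tied-score blocks inherit the first member's group
    ss = s[order]
    block_start = np.flatnonzero(np.r_[True, np.diff(ss) != 0])
    block_id = np.cumsum(np.r_[True, np.diff(ss) != 0]) - 1
    grp = grp[block_start][block_id]
    out = np.empty(len(s), dtype=int)
    out[order] = grp
    return pd.Categorical.from_codes(out, categories=labels, ordered=True)


def add_wealth_index(
    ds: SurveyDataset, by: str | None = None
) -> WealthIndexResult:
    """Fit the wealth index on a dataset, adding ``wealth_score`` and
    ``wealth_quintile`` columns in place.

    ``by`` names an optional grouping column (e.g. country): the PCA is
    then fit separately per group and scores concatenated, mirroring
    country-specific index construction; quintiles are always assigned on
    the pooled score distribution. The returned result carries the pooled
    quintiles and, for grouped fits, the loadings of the largest group.
    """
    df = ds.table
    w = ds.weights
    assets = df[ds.config.asset_cols]
    if by is None:
        res = pca_wealth_score(assets, w)
        score = res.score
    else:
        score = np.empty(len(df))
        results: dict = {}
        for g, idx in df.groupby(by, sort=True).indices.items():
            results[g] = pca_wealth_score(assets.iloc[idx], w[idx])
            score[idx] = results[g].score
        largest = max(results, key=lambda g: len(df.groupby(by).indices[g]))
        res = results[largest]
        res = WealthIndexResult(
            score=score,
            loadings=res.loadings,
            explained_variance_ratio=res.explained_variance_ratio,
            orientation_flipped=res.orientation_flipped,
            dropped_assets=res.dropped_assets,
        )
    quint = assign_quintiles(score, w)
    df["wealth_score"] = score
    df["wealth_quintile"] = quint
    res.score = score
    res.quintile = quint
    return res
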