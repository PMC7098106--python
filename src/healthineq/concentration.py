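"""Concentration indices over the wealth distribution.

The concentration index of an outcome y with respect to a wealth ranking
is twice the weighted covariance between y and the fractional wealth rank,
divided by the mean of y:

    Conc.I = 2 * cov_w(y, r) / ybar,

where the fractional rank r_i = (cumulative weight of all strictly poorer
individuals + w_i/2) / total weight (tied wealth values share their
block's midpoint rank; the weighted mean of r is exactly 0.5). Negative
values indicate concentration among the poor (pro-poor), positive among
the rich (pro-rich). For a binary outcome Conc.I is bounded by
[ybar-1, 1-ybar], so the Erreygers correction E = 4*ybar*Conc.I (the
outcome range is 1) restores a fixed [-1, 1] range and the exact mirror
property E(1-y) = -E(y); the Wagstaff normalisation Conc.I/(1-ybar) is the
usual robustness companion.

Uncertainty comes either from the cluster-robust "convenient regression"
(WLS of 2*var(r)/ybar * y on r, PSU-clustered standard errors) or from a
within-stratum PSU bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .io import SurveyDataset

logger = logging.getLogger(__name__)


@dataclass
class ConcentrationResult:
    mean_outcome: float
    conc_i: float
    erreygers: float
    wagstaff: float
    se_conc_i: float
    n_effective: float
    method_se: str
    ci95_conc_i: tuple[float, float] | None = None
    ci95_erreygers: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_outcome": self.mean_outcome,
            "conc_i": self.conc_i,
            "erreygers": self.erreygers,
            "wagstaff": self.wagstaff,
            "se_conc_i": self.se_conc_i,
            "n_effective": self.n_effective,
            "method_se": self.method_se,
        }
        if self.ci95_conc_i is not None:
            d["ci95_conc_i"] = list(self.ci95_conc_i)
        if self.ci95_erreygers is not None:
            d["ci95_erreygers"] = list(self.ci95_erreygers)
        return d


def _check_weights(w: np.ndarray) -> None:
    if np.any(w <= 0) or np.any(~np.isfinite(w)):
        raise ValueError("weights must be finite and strictly positive")


def fractional_rank(ranking_var: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted fractional rank in the distribution of ``ranking_var``.

    r_i = (cumulative weight strictly below i + w_i/2) / total weight, with
    tied ranking values sharing their tied block's midpoint. The weighted
    mean of the returned ranks is exactly 0.5.
    """
    x = np.asarray(ranking_var, float)
    w = np.asarray(weights, float)
    if x.size == 0:
        raise ValueError("empty input")
    if np.any(~np.isfinite(x)):
        raise ValueError("ranking variable must be finite")
    _check_weights(w)
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    W = ws.sum()
    new_block = np.r_[True, np.diff(xs) != 0]
    block_id = np.cumsum(new_block) - 1
    block_w = np.bincount(block_id, weights=ws)
    cum_before = np.r_[0.0, np.cumsum(block_w)[:-1]]
    r_block = (cum_before + block_w / 2.0) / W
    out = np.empty_like(x)
    out[order] = r_block[block_id]
    return out


def weighted_cov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted population covariance (divide by total weight)."""
    W = w.sum()
    xm = np.sum(w * x) / W
    ym = np.sum(w * y) / W
    return float(np.sum(w * (x - xm) * (y - ym)) / W)


def concentration_index(y: np.ndarray, rank: np.ndarray, weights: np.ndarray) -> float:
    """Standard concentration index 2*cov_w(y, rank)/ybar.

    A constant outcome has zero covariance and returns 0.0 with a warning;
    a zero-mean outcome leaves the index undefined and raises.
    """
    y = np.asarray(y, float)
    r = np.asarray(rank, float)
    w = np.asarray(weights, float)
    _check_weights(w)
    W = w.sum()
    ybar = float(np.sum(w * y) / W)
    if ybar == 0.0:
        raise ValueError("undefined index, zero mean outcome")
    if np.all(y == y[0]):
        warnings.warn("constant outcome: concentration index is 0", stacklevel=2)
        return 0.0
    return 2.0 * weighted_cov(y, r, w) / ybar


def _require_binary(y: np.ndarray) -> None:
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary (0/1)")


def erreygers_index(y: np.ndarray, rank: np.ndarray, weights: np.ndarray) -> float:
    """Erreygers-corrected index for a binary outcome: E = 4*ybar*Conc.I."""
    y = np.asarray(y, float)
    _require_binary(y)
    w = np.asarray(weights, float)
    ybar = float(np.sum(w * y) / w.sum())
    if ybar == 0.0:
        return 0.0  # no cases: no inequality to apportion
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ci = concentration_index(y, rank, w)
    return 4.0 * ybar * ci


def wagstaff_index(y: np.ndarray, rank: np.ndarray, weights: np.ndarray) -> float:
    """Wagstaff-normalised index for a binary outcome: Conc.I/(1-ybar)."""
    y = np.asarray(y, float)
    _require_binary(y)
    w = np.asarray(weights, float)
    ybar = float(np.sum(w * y) / w.sum())
    if ybar in (0.0, 1.0):
        raise ValueError("Wagstaff index undefined for degenerate mean outcome")
    return concentration_index(y, rank, w) / (1.0 - ybar)


def kish_n_effective(weights: np.ndarray) -> float:
    w = np.asarray(weights, float)
    return float(w.sum() ** 2 / np.sum(w ** 2))


def _analytic_se(
    y: np.ndarray, r: np.ndarray, w: np.ndarray, psu: np.ndarray
) -> float:
    """Cluster-robust SE of Conc.I from the convenient WLS regression.

    Regressing 2*var_w(r)/ybar * y on r with analytic weights gives a slope
    equal to the covariance-form index; PSU-clustered robust covariance
    supplies the standard error.
    """
    W = w.sum()
    ybar = np.sum(w * y) / W
    rbar = np.sum(w * r) / W
    var_r = np.sum(w * (r - rbar) ** 2) / W
    lhs = (2.0 * var_r / ybar) * y
    X = sm.add_constant(r)
    res = sm.WLS(lhs, X, weights=w).fit(
        cov_type="cluster", cov_kwds={"groups": psu}
    )
    return float(res.bse[1])


def bootstrap_se(
    ds: SurveyDataset,
    outcome: str,
    rank_by: str = "wealth_score",
    n_reps: int = 200,
    seed: int = 0,
) -> tuple[float, tuple[float, float], np.ndarray]:
    """Within-stratum PSU cluster bootstrap of the concentration index.

    PSUs are resampled with replacement within each stratum; ranks and the
    index are recomputed on every replicate. Returns the bootstrap SE, the
    percentile 95% interval and the replicate values.
    """
    df = ds.table
    cfg = ds.config
    if df[cfg.psu_col].nunique() < 2:
        raise ValueError("cluster bootstrap needs at least 2 PSUs")
    rng = np.random.default_rng(seed)
    groups: dict = {}
    for (s, _), idx in df.groupby(
        [cfg.stratum_col, cfg.psu_col], sort=True
    ).indices.items():
        groups.setdefault(s, []).append(idx)
    y_all = df[outcome].to_numpy(float)
    x_all = df[rank_by].to_numpy(float)
    w_all = df[cfg.weight_col].to_numpy(float)
    reps = np.empty(n_reps)
    for b in range(n_reps):
        take: list[np.ndarray] = []
        for s, psu_indices in groups.items():
            k = len(psu_indices)
            for j in rng.integers(0, k, k):
                take.append(psu_indices[j])
        idx = np.concatenate(take)
        r = fractional_rank(x_all[idx], w_all[idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reps[b] = concentration_index(y_all[idx], r, w_all[idx])
    se = float(np.std(reps, ddof=1))
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return se, (float(lo), float(hi)), reps


def concentration_summary(
    ds: SurveyDataset,
    outcome: str,
    rank_by: str = "wealth_score",
    se_method: str = "analytic",
    n_reps: int = 200,
    seed: int = 0,
) -> ConcentrationResult:
    """All concentration-index quantities for one outcome of a dataset."""
    df = ds.table
    y = df[outcome].to_numpy(float)
    w = ds.weights
    r = fractional_rank(df[rank_by].to_numpy(float), w)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ci = concentration_index(y, r, w)
    ybar = float(np.sum(w * y) / w.sum())
    err = erreygers_index(y, r, w)
    wag = wagstaff_index(y, r, w) if 0.0 < ybar < 1.0 else float("nan")
    ci95_ci = ci95_e = None
    if se_method == "bootstrap":
        se, ci95_ci, reps = bootstrap_se(ds, outcome, rank_by, n_reps=n_reps, seed=seed)
        e_reps = 4.0 * ybar * reps  # mean held at the point estimate
        lo, hi = np.percentile(e_reps, [2.5, 97.5])
        ci95_e = (float(lo), float(hi))
    elif se_method == "analytic":
        se = _analytic_se(y, r, w, df[ds.config.psu_col].to_numpy())
    elif se_method == "none":
        se = float("nan")
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return ConcentrationResult(
        mean_outcome=ybar,
        conc_i=ci,
        erreygers=err,
        wagstaff=wag,
        se_conc_i=se,
        n_effective=kish_n_effective(w),
        method_se=se_method,
        ci95_conc_i=ci95_ci,
        ci95_erreygers=ci95_e,
    )
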