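"""Regression-based decomposition of the Erreygers index.

A weighted logistic regression of the binary outcome on the covariates
supplies, for each factor k, a marginal effect beta_k^m (by default the
average partial effect beta_k * mean_w[p_i(1-p_i)]). The Erreygers index
then decomposes as

    E = 4 * sum_k beta_k^m * xbar_k * Conc.I_k  +  residual,

where xbar_k is the weighted mean of covariate k and Conc.I_k its own
concentration index over the wealth rank. Each factor's absolute
contribution is computed in the covariance form 8 * beta_k^m * cov_w(x_k, r)
(identical to the product form whenever xbar_k != 0, and well defined when
it is 0); the residual is total E minus the sum of contributions, so
additivity holds to machine precision by construction. Relative
contributions are percentages of total E; their sum is the explained share.

A factor concentrated among the poor (Conc.I_k < 0) with a positive
marginal effect therefore carries a negative contribution — it offsets
pro-rich inequality — matching the usual narrative reading of such tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .concentration import concentration_index, erreygers_index, fractional_rank, weighted_cov
from .io import SurveyDataset

logger = logging.getLogger(__name__)

#: |coefficient| beyond which the logit fit is treated as separated.
SEPARATION_THRESHOLD = 15.0


@dataclass
class LogitFit:
    coef: dict[str, float]
    or_: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    converged: bool
    n_used: int
    fitted_p: np.ndarray
    weights: np.ndarray
    dropped: list[str] = field(default_factory=list)


@dataclass
class FactorRow:
    name: str
    coef: float
    or_: float
    elasticity: float
    factor_conc_i: float
    contribution_abs: float
    contribution_rel_pct: float
    ci95_rel: tuple[float, float] | None = None


@dataclass
class DecompositionResult:
    factors: list[FactorRow]
    residual_abs: float
    total_erreygers: float
    explained_pct: float
    mean_outcome: float
    marginal_effect_kind: str = "ape"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": f.name,
                "coef": f.coef,
                "OR": f.or_,
                "elasticity": f.elasticity,
                "conc_i": f.factor_conc_i,
                "contribution_abs": f.contribution_abs,
                "contribution_rel_pct": f.contribution_rel_pct,
                "rel_ci95_low": f.ci95_rel[0] if f.ci95_rel else np.nan,
                "rel_ci95_high": f.ci95_rel[1] if f.ci95_rel else np.nan,
            }
            for f in self.factors
        ]
        rows.append({
            "factor": "residual",
            "contribution_abs": self.residual_abs,
            "contribution_rel_pct": 100.0 - self.explained_pct,
        })
        rows.append({
            "factor": "total",
            "contribution_abs": self.total_erreygers,
            "contribution_rel_pct": self.explained_pct,
        })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "factors": {
                f.name: {
                    "coef": f.coef,
                    "or": f.or_,
                    "elasticity": f.elasticity,
                    "conc_i": f.factor_conc_i,
                    "contribution_abs": f.contribution_abs,
                    "contribution_rel_pct": f.contribution_rel_pct,
                    "ci95_rel": list(f.ci95_rel) if f.ci95_rel else None,
                }
                for f in self.factors
            },
            "residual_abs": self.residual_abs,
            "total_erreygers": self.total_erreygers,
            "explained_pct": self.explained_pct,
            "mean_outcome": self.mean_outcome,
            "marginal_effect_kind": self.marginal_effect_kind,
        }

    def factor(self, name: str) -> FactorRow:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


class SeparationError(RuntimeError):
    pass


def _drop_collinear(X: pd.DataFrame) -> pd.DataFrame:
    """Drop columns until the design matrix (with intercept) is full rank."""
    M = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    if np.linalg.matrix_rank(M) == M.shape[1]:
        return X
    keep: list[str] = []
    base = np.ones((len(X), 1))
    for c in X.columns:
        cand = np.column_stack([base, X[c].to_numpy(float)])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            base = cand
            keep.append(c)
        else:
            logger.warning("fit_logit: dropping collinear column %r", c)
    return X[keep]


def fit_logit(
    ds: SurveyDataset | pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    weight_col: str | None = None,
) -> LogitFit:
    """Weighted maximum-likelihood logistic regression.

    Sampling weights enter as frequency-style analytic weights (GLM
    ``var_weights``), normalised to mean one so that estimates *and*
    confidence intervals are invariant to rescaling all weights.
    Collinear columns are dropped with a log entry; a coefficient beyond
    ``SEPARATION_THRESHOLD`` in absolute value signals (quasi-)separation
    and raises, naming the offending covariate.
    """
    if isinstance(ds, SurveyDataset):
        df = ds.table
        weight_col = weight_col or ds.config.weight_col
    else:
        df = ds
        if weight_col is None:
            raise ValueError("weight_col required with a bare DataFrame")
    y = df[outcome].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary (0/1)")
    if np.all(y == y[0]):
        raise ValueError("outcome is constant; logit undefined")
    w = df[weight_col].to_numpy(float)
    w = w / w.mean()
    X = _drop_collinear(df[list(covariates)].astype(float))
    dropped = [c for c in covariates if c not in X.columns]
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, Xc, family=sm.families.Binomial(), var_weights=w)
        res = model.fit(maxiter=200)
    params = res.params
    bad = params.index[np.abs(params.to_numpy()) > SEPARATION_THRESHOLD].tolist()
    if bad:
        raise SeparationError(f"possible separation: covariate(s) {bad}")
    conf = res.conf_int()
    coef = {k: float(v) for k, v in params.items()}
    return LogitFit(
        coef=coef,
        or_={k: float(np.exp(v)) for k, v in coef.items()},
        ci95={k: (float(conf.loc[k, 0]), float(conf.loc[k, 1])) for k in params.index},
        converged=bool(res.converged),
        n_used=len(y),
        fitted_p=np.asarray(res.fittedvalues, float),
        weights=w,
        dropped=dropped,
    )


def marginal_effect(fit: LogitFit, kind: str = "ape") -> dict[str, float]:
    """Marginal effects beta_k^m of a logit fit.

    ``kind='ape'`` (default): average partial effect
    beta_k * mean_w[p_i(1-p_i)]; ``kind='at_mean'``: effect at the mean
    fitted probability, beta_k * pbar(1-pbar).
    """
    if not fit.converged:
        raise ValueError("marginal effects require a converged fit")
    p = fit.fitted_p
    w = fit.weights
    if kind == "ape":
        scale = float(np.sum(w * p * (1.0 - p)) / w.sum())
    elif kind == "at_mean":
        pbar = float(np.sum(w * p) / w.sum())
        scale = pbar * (1.0 - pbar)
    else:
        raise ValueError(f"unknown marginal effect kind {kind!r}")
    return {k: b * scale for k, b in fit.coef.items() if k != "const"}


def decompose_erreygers(
    ds: SurveyDataset,
    outcome: str,
    covariates: Sequence[str],
    rank_by: str = "wealth_score",
    marginal_kind: str = "ape",
    fit: LogitFit | None = None,
) -> DecompositionResult:
    """Decompose the Erreygers index of ``outcome`` into factor contributions.

    ``rank_by`` names the wealth score column used for fractional ranking.
    Pass a pre-computed ``fit`` to reuse a logistic fit (the bootstrap does).
    """
    df = ds.table
    w = ds.weights
    W = w.sum()
    y = df[outcome].to_numpy(float)
    r = fractional_rank(df[rank_by].to_numpy(float), w)
    total_e = erreygers_index(y, r, w)
    ybar = float(np.sum(w * y) / W)
    if fit is None:
        fit = fit_logit(ds, outcome, covariates)
    me = marginal_effect(fit, kind=marginal_kind)

    factors: list[FactorRow] = []
    contrib_sum = 0.0
    for name in covariates:
        if name in fit.dropped:
            continue
        x = df[name].to_numpy(float)
        xbar = float(np.sum(w * x) / W)
        bm = me[name]
        cov_xr = weighted_cov(x, r, w)
        contribution = 8.0 * bm * cov_xr
        sd_x = float(np.sqrt(np.sum(w * (x - xbar) ** 2) / W))
        if np.all(x == x[0]):
            fci = 0.0
        elif abs(xbar) > 1e-10 * max(1.0, sd_x):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fci = concentration_index(x, r, w)
        else:
            # mean-centred covariate (e.g. a PCA score): its own concentration
            # index is undefined, though the contribution (covariance form) is not
            fci = float("nan")
        contrib_sum += contribution
        factors.append(FactorRow(
            name=name,
            coef=fit.coef[name],
            or_=fit.or_[name],
            elasticity=bm * xbar / ybar,
            factor_conc_i=fci,
            contribution_abs=contribution,
            contribution_rel_pct=np.nan,
        ))
    residual = total_e - contrib_sum
    if total_e == 0.0:
        raise ValueError(
            "total Erreygers index is zero: relative contributions undefined; "
            "report absolute contributions only"
        )
    for f in factors:
        f.contribution_rel_pct = 100.0 * f.contribution_abs / total_e
    explained = 100.0 * contrib_sum / total_e
    return DecompositionResult(
        factors=factors,
        residual_abs=residual,
        total_erreygers=total_e,
        explained_pct=explained,
        mean_outcome=ybar,
        marginal_effect_kind=marginal_kind,
    )


def bootstrap_contributions(
    ds: SurveyDataset,
    outcome: str,
    covariates: Sequence[str],
    rank_by: str = "wealth_score",
    n_reps: int = 200,
    seed: int = 0,
    marginal_kind: str = "ape",
) -> dict[str, tuple[float, float]]:
    """Percentile 95% CIs of relative contributions by PSU cluster bootstrap.

    PSUs are resampled with replacement within strata and the entire
    decomposition (ranking, logit fit, contributions) is recomputed per
    replicate. Replicates with a non-convergent or separated fit are
    dropped and counted; more than 20% dropped raises.
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
    reps: dict[str, list[float]] = {c: [] for c in covariates}
    reps["_explained"] = []
    n_dropped = 0
    for _ in range(n_reps):
        take = []
        for s, psu_indices in groups.items():
            k = len(psu_indices)
            for j in rng.integers(0, k, k):
                take.append(psu_indices[j])
        idx = np.concatenate(take)
        boot = SurveyDataset(df.iloc[idx].reset_index(drop=True), cfg)
        try:
            res = decompose_erreygers(
                boot, outcome, covariates, rank_by=rank_by, marginal_kind=marginal_kind
            )
        except (SeparationError, ValueError):
            n_dropped += 1
            continue
        if not all(np.isfinite(f.contribution_rel_pct) for f in res.factors):
            n_dropped += 1
            continue
        for f in res.factors:
            reps[f.name].append(f.contribution_rel_pct)
        reps["_explained"].append(res.explained_pct)
    if n_dropped > 0.2 * n_reps:
        raise RuntimeError(
            f"{n_dropped}/{n_reps} bootstrap replicates dropped (non-convergent fits)"
        )
    if n_dropped:
        logger.info("bootstrap_contributions: dropped %d replicates", n_dropped)
    out: dict[str, tuple[float, float]] = {}
    for name, vals in reps.items():
        if vals:
            lo, hi = np.percentile(vals, [2.5, 97.5])
            out[name] = (float(lo), float(hi))
    return out


def attach_bootstrap_cis(
    res: DecompositionResult, cis: Mapping[str, tuple[float, float]]
) -> DecompositionResult:
    """Return a copy of ``res`` with per-factor bootstrap CIs attached."""
    factors = [replace(f, ci95_rel=cis.get(f.name)) for f in res.factors]
    return replace(res, factors=factors)
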