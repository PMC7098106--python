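"""Synthetic stratified two-stage cluster surveys with latent-wealth assets.

The generator emulates the design of a Demographic and Health Survey:
within each stratum, primary sampling units (PSUs, enumeration areas) are
selected from a frame with probability proportional to size by systematic
sampling, then a fixed number of households is selected within each sampled
PSU by equal-probability systematic sampling, and every eligible woman in a
selected household is interviewed. Sampling weights are the exact inverse
of the product of the two stage-selection probabilities, which the table
stores so the design can be audited row by row.

Household wealth is a latent standard-normal variable split into a PSU
component and a household component so that the intracluster correlation of
wealth equals the requested ``icc`` exactly in expectation. Dichotomous
asset indicators load on latent wealth through seeded logistic models
(positive slopes, so a first principal component is recoverable), and
binary outcomes are drawn from user-set logistic models on the generated
covariates and latent wealth.

The classical optimal-allocation formulas for a two-stage design are also
housed here: the optimal cluster take ``m_opt = sqrt((1-rho)*c1 / (rho*c2))``
and the number of PSUs affordable at total cost ``C``,
``n_opt = C / (c1 + c2*m)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import ColumnConfig, SurveyDataset

#: Covariates the generator always produces (woman-level unless noted).
GENERATED_COVARIATES = (
    "age_years",
    "schooling_years",
    "household_size",
    "urban",
    "media_exposure",
    "insured",
    "married",
    "employed",
)


@dataclass(frozen=True)
class DesignParams:
    """Parameters of the stratified two-stage cluster design.

    ``icc`` is the intracluster correlation of latent wealth (share of
    wealth variance between PSUs); ``cost_psu``/``cost_interview`` are the
    per-PSU and per-interview unit costs (c1, c2) used by the allocation
    formulas.
    """

    n_strata: int = 2
    psus_per_stratum: int = 25
    households_per_psu: int = 20
    women_per_household_mean: float = 1.0
    icc: float = 0.3
    cost_psu: float = 4.0
    cost_interview: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.icc < 1.0):
            raise ValueError(f"icc must lie strictly in (0, 1), got {self.icc}")
        for name in ("n_strata", "psus_per_stratum", "households_per_psu"):
            v = getattr(self, name)
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v}")
        if self.women_per_household_mean < 1.0:
            raise ValueError("women_per_household_mean must be >= 1")
        if self.cost_psu <= 0 or self.cost_interview <= 0:
            raise ValueError("costs must be strictly positive")
        if self.n_strata * self.psus_per_stratum * self.households_per_psu < 2:
            raise ValueError("degenerate design: fewer than two women in total")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for a binary outcome on generated covariates.

    The linear predictor is ``intercept + sum_k coef[k]*x_k +
    wealth_coef * latent_wealth`` (latent wealth is ~N(0,1)); the outcome is
    Bernoulli(logistic(linear predictor)). Every key of ``coef`` must name a
    generated covariate column.
    """

    intercept: float = 0.0
    coef: Mapping[str, float] = field(default_factory=dict)
    wealth_coef: float = 0.0

    def __post_init__(self) -> None:
        bad = [k for k in self.coef if k not in GENERATED_COVARIATES]
        if bad:
            raise ValueError(
                f"coef keys must be generated covariates {GENERATED_COVARIATES}; bad: {bad}"
            )


def default_outcome_models() -> dict[str, OutcomeModel]:
    """Outcome models emulating pooled CCS knowledge (~37%) and
    utilisation (~29%) prevalences with a pro-rich wealth gradient."""
    return {
        "outcome_knowledge": OutcomeModel(
            intercept=-1.3,
            coef={"schooling_years": 0.08, "media_exposure": 0.4, "urban": 0.2},
            wealth_coef=0.5,
        ),
        "outcome_utilisation": OutcomeModel(
            intercept=-1.4,
            coef={"insured": 0.4, "married": 0.3, "urban": 0.2},
            wealth_coef=0.6,
        ),
    }


def optimal_cluster_size(icc: float, cost_psu: float, cost_interview: float) -> float:
    """Optimal number of interviews per PSU, sqrt(((1-rho)*c1)/(rho*c2)).

    Balances the cost ratio c1/c2 against the intracluster correlation rho:
    cheap clusters or low correlation favour larger takes.
    """
    if not (0.0 < icc < 1.0):
        raise ValueError(f"icc must lie strictly in (0, 1), got {icc}")
    if cost_psu <= 0 or cost_interview <= 0:
        raise ValueError("costs must be strictly positive")
    return math.sqrt(((1.0 - icc) * cost_psu) / (icc * cost_interview))


def survey_cost(n_psus: float, m: float, cost_psu: float, cost_interview: float) -> float:
    """Total cost C = c1*n + c2*n*m of fielding n PSUs with take m."""
    return cost_psu * n_psus + cost_interview * n_psus * m


def required_psus(total_cost: float, cost_psu: float, cost_interview: float, m: float) -> float:
    """Number of PSUs affordable at total cost C: n = C / (c1 + c2*m)."""
    if total_cost <= 0 or cost_psu <= 0 or cost_interview <= 0 or m <= 0:
        raise ValueError("all inputs must be strictly positive")
    return total_cost / (cost_psu + cost_interview * m)


def _systematic_pps(sizes: np.ndarray, n_select: int, rng: np.random.Generator) -> np.ndarray:
    """Systematic PPS sample of ``n_select`` units; returns selected indices.

    Requires every size < sampling interval so each unit can be hit at most
    once; inclusion probability is then exactly n_select*size/total.
    """
    total = sizes.sum()
    interval = total / n_select
    if sizes.max() >= interval:
        raise ValueError("PSU frame size exceeds PPS sampling interval")
    start = rng.uniform(0.0, interval)
    points = start + interval * np.arange(n_select)
    cum = np.cumsum(sizes)
    return np.searchsorted(cum, points, side="right")


def simulate_survey(
    design: DesignParams,
    n_assets: int = 10,
    outcome_models: Mapping[str, OutcomeModel] | None = None,
    *,
    asset_intercepts: np.ndarray | None = None,
    asset_slopes: np.ndarray | None = None,
) -> SurveyDataset:
    """Draw one stratified two-stage cluster sample with known ground truth.

    Returns a :class:`~healthineq.io.SurveyDataset` whose table carries, per
    woman: ids (stratum, PSU, household, woman), the exact design weight and
    its two stage-selection probabilities, the latent wealth (simulation
    truth), ``n_assets`` binary asset indicators, the generated covariates
    and one 0/1 column per outcome model.

    Asset k is owned with probability logistic(a_k + b_k * wealth); by
    default intercepts a_k are drawn uniformly on [-1.5, 1.5] and slopes b_k
    on [0.5, 2.0] (all positive, so the first principal component of the
    asset matrix recovers wealth). Pass explicit arrays to override.
    """
    if n_assets < 2:
        raise ValueError("n_assets must be >= 2")
    if outcome_models is None:
        outcome_models = default_outcome_models()
    rng = np.random.default_rng(design.seed)

    a = (rng.uniform(-1.5, 1.5, n_assets) if asset_intercepts is None
         else np.asarray(asset_intercepts, float))
    b = (rng.uniform(0.5, 2.0, n_assets) if asset_slopes is None
         else np.asarray(asset_slopes, float))
    if len(a) != n_assets or len(b) != n_assets:
        raise ValueError("asset parameter arrays must have length n_assets")

    m_take = design.households_per_psu
    size_lo = max(80, 2 * m_take)
    size_hi = size_lo + 150
    frame_per_stratum = 8 * design.psus_per_stratum

    recs: list[pd.DataFrame] = []
    woman0 = 0
    for s in range(design.n_strata):
        sizes = rng.integers(size_lo, size_hi + 1, frame_per_stratum).astype(float)
        total_hh = sizes.sum()
        sel = _systematic_pps(sizes, design.psus_per_stratum, rng)
        for j, frame_idx in enumerate(sel):
            m_j = sizes[frame_idx]
            p1 = design.psus_per_stratum * m_j / total_hh
            p2 = m_take / m_j
            weight = 1.0 / (p1 * p2)
            u_psu = rng.normal(0.0, math.sqrt(design.icc))
            n_hh = m_take
            e_hh = rng.normal(0.0, math.sqrt(1.0 - design.icc), n_hh)
            wealth_hh = u_psu + e_hh
            if design.women_per_household_mean == 1.0:
                women_per_hh = np.ones(n_hh, dtype=int)
            else:
                women_per_hh = 1 + rng.poisson(design.women_per_household_mean - 1.0, n_hh)
            n_w = int(women_per_hh.sum())
            hh_of_woman = np.repeat(np.arange(n_hh), women_per_hh)
            wealth = wealth_hh[hh_of_woman]
            assets = (rng.random((n_hh, n_assets)) < expit(a + np.outer(wealth_hh, b)))
            assets = assets[hh_of_woman].astype(np.int8)

            cov = {
                "age_years": rng.integers(15, 50, n_w).astype(float),
                "schooling_years": np.clip(
                    np.rint(rng.normal(6.0 + 2.0 * wealth, 3.0)), 0, 18
                ),
                "household_size": (1 + rng.poisson(4.0, n_w)).astype(float),
                "urban": (rng.random(n_w) < expit(-0.5 + 1.0 * wealth)).astype(np.int8),
                "media_exposure": (rng.random(n_w) < expit(0.3 + 0.8 * wealth)).astype(np.int8),
                "insured": (rng.random(n_w) < expit(-1.2 + 0.6 * wealth)).astype(np.int8),
                "married": (rng.random(n_w) < 0.8).astype(np.int8),
                "employed": (rng.random(n_w) < 0.5).astype(np.int8),
            }

            df = pd.DataFrame({
                "woman_id": np.arange(woman0, woman0 + n_w),
                "stratum_id": s,
                "psu_id": s * design.psus_per_stratum + j,
                "household_id": hh_of_woman,
                "stage1_prob": p1,
                "stage2_prob": p2,
                "weight": weight,
                "latent_wealth": wealth,
            })
            woman0 += n_w
            for k in range(n_assets):
                df[f"asset_{k}"] = assets[:, k]
            for name, vals in cov.items():
                df[name] = vals
            for oname, model in outcome_models.items():
                lp = model.intercept + model.wealth_coef * wealth
                for cname, beta in model.coef.items():
                    lp = lp + beta * np.asarray(cov[cname], float)
                df[oname] = (rng.random(n_w) < expit(lp)).astype(np.int8)
            recs.append(df)

    table = pd.concat(recs, ignore_index=True)
    config = ColumnConfig(
        weight_col="weight",
        psu_col="psu_id",
        stratum_col="stratum_id",
        outcome_cols=list(outcome_models),
        asset_cols=[f"asset_{k}" for k in range(n_assets)],
        covariate_cols=list(GENERATED_COVARIATES),
        weight_scale="natural",
    )
    return SurveyDataset(table, config)
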