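"""Logistic fit, marginal effects and the Erreygers decomposition."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import healthineq as hi

COVS = ["age_years", "urban", "insured", "married", "employed", "wealth_score"]


@pytest.fixture(scope="module")
def decomposed(wealth_ds):
    return hi.decompose_erreygers(wealth_ds, "outcome_utilisation", COVS)


class TestFitLogit:
    def test_direction_of_a_true_driver(self, wealth_ds):
        fit = hi.fit_logit(wealth_ds, "outcome_utilisation", ["wealth_score"])
        assert fit.or_["wealth_score"] > 1.0
        assert fit.converged

    def test_or_is_exp_coef(self, wealth_ds):
        fit = hi.fit_logit(wealth_ds, "outcome_utilisation", ["wealth_score", "urban"])
        for k, b in fit.coef.items():
            assert fit.or_[k] == pytest.approx(np.exp(b), rel=1e-10)

    def test_recovers_generator_coefficient(self):
        ds = hi.simulate_survey(
            hi.DesignParams(n_strata=2, psus_per_stratum=100, households_per_psu=250, seed=13),
            outcome_models={"y": hi.OutcomeModel(intercept=-0.5, wealth_coef=0.7)},
        )
        fit = hi.fit_logit(ds, "y", ["latent_wealth"])
        assert fit.coef["latent_wealth"] == pytest.approx(0.7, abs=0.1)

    def test_null_coefficients_within_three_se(self):
        """Calibration: with all true effects 0, |coef| < 3*SE nearly always."""
        checks = ok = 0
        covs = ["age_years", "married", "employed", "household_size", "urban"]
        for seed in range(20):
            ds = hi.simulate_survey(
                hi.DesignParams(n_strata=2, psus_per_stratum=25,
                                households_per_psu=200, seed=seed),
                outcome_models={"y": hi.OutcomeModel(intercept=0.0, wealth_coef=0.0)},
            )
            fit = hi.fit_logit(ds, "y", covs)
            for c in covs:
                lo, hi_ = fit.ci95[c]
                # 95% CI from +-1.96 SE; widen to 3 SE
                se = (hi_ - lo) / (2 * 1.959963984540054)
                checks += 1
                ok += abs(fit.coef[c]) < 3 * se
        assert ok / checks >= 0.90

    def test_collinear_column_dropped(self, wealth_ds):
        df = wealth_ds.table.copy()
        df["urban_copy"] = df["urban"]
        ds = hi.SurveyDataset(df, wealth_ds.config)
        fit = hi.fit_logit(ds, "outcome_utilisation", ["urban", "urban_copy", "wealth_score"])
        assert "urban_copy" in fit.dropped

    def test_separation_detected(self):
        n = 200
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "y": np.r_[np.zeros(100), np.ones(100)],
            "x": np.r_[np.zeros(100), np.ones(100)],
            "noise": rng.normal(size=n),
            "w": np.ones(n),
        })
        with pytest.raises(hi.SeparationError, match="x"):
            hi.fit_logit(df, "y", ["x", "noise"], weight_col="w")

    def test_non_binary_outcome_rejected(self, wealth_ds):
        with pytest.raises(ValueError, match="binary"):
            hi.fit_logit(wealth_ds, "age_years", ["urban"])

    def test_weight_scale_invariance_including_cis(self, wealth_ds):
        df = wealth_ds.table.copy()
        df["weight"] = df["weight"] * 1e6
        ds = hi.SurveyDataset(df, wealth_ds.config)
        a = hi.fit_logit(wealth_ds, "outcome_utilisation", ["wealth_score"])
        b = hi.fit_logit(ds, "outcome_utilisation", ["wealth_score"])
        assert a.coef["wealth_score"] == pytest.approx(b.coef["wealth_score"], rel=1e-10)
        assert a.ci95["wealth_score"] == pytest.approx(b.ci95["wealth_score"], rel=1e-8)


class TestMarginalEffect:
    def test_zero_coef_zero_effect(self, wealth_ds):
        fit = hi.fit_logit(wealth_ds, "outcome_utilisation", ["wealth_score", "married"])
        fit.coef["married"] = 0.0
        assert hi.marginal_effect(fit)["married"] == 0.0

    def test_intercept_only_scaling_quarter(self):
        # ybar = 0.5 exactly -> p(1-p) = 0.25 exactly
        df = pd.DataFrame({"y": [0, 1] * 50, "x": 0.0, "w": 1.0})
        df["x"] = np.tile([0.0, 1.0, 1.0, 0.0], 25)  # balanced against y
        fit = hi.fit_logit(df, "y", ["x"], weight_col="w")
        p = fit.fitted_p
        assert np.average(p * (1 - p), weights=fit.weights) == pytest.approx(0.25, abs=1e-10)

    def test_ape_matches_finite_difference(self, wealth_ds):
        covs = ["wealth_score", "urban", "age_years"]
        sub = wealth_ds.table.iloc[:50]
        ds = hi.SurveyDataset(sub.reset_index(drop=True), wealth_ds.config)
        fit = hi.fit_logit(ds, "outcome_utilisation", covs)
        me = hi.marginal_effect(fit, kind="ape")
        X = ds.table[covs].to_numpy(float)
        w = fit.weights
        beta = np.array([fit.coef[c] for c in covs])
        b0 = fit.coef["const"]
        h = 1e-5
        for j, c in enumerate(covs):
            Xp, Xm = X.copy(), X.copy()
            Xp[:, j] += h / 2
            Xm[:, j] -= h / 2
            fd = (expit(b0 + Xp @ beta) - expit(b0 + Xm @ beta)) / h
            assert me[c] == pytest.approx(float(np.average(fd, weights=w)), abs=1e-6)

    def test_at_mean_uses_mean_probability(self, wealth_ds):
        fit = hi.fit_logit(wealth_ds, "outcome_utilisation", ["wealth_score"])
        me = hi.marginal_effect(fit, kind="at_mean")
        pbar = np.average(fit.fitted_p, weights=fit.weights)
        assert me["wealth_score"] == pytest.approx(fit.coef["wealth_score"] * pbar * (1 - pbar))


class TestDecomposition:
    def test_exact_additivity(self, decomposed):
        total = sum(f.contribution_abs for f in decomposed.factors) + decomposed.residual_abs
        assert total == pytest.approx(decomposed.total_erreygers, abs=1e-10)

    def test_relative_contributions_sum_to_explained(self, decomposed):
        assert sum(f.contribution_rel_pct for f in decomposed.factors) == pytest.approx(
            decomposed.explained_pct, abs=1e-8
        )

    def test_constant_covariate_contributes_exactly_zero(self, wealth_ds):
        df = wealth_ds.table.copy()
        df["const_cov"] = 1.0
        ds = hi.SurveyDataset(df, wealth_ds.config)
        res = hi.decompose_erreygers(
            ds, "outcome_utilisation", ["wealth_score", "const_cov"]
        )
        # a constant is collinear with the intercept and carries no signal
        names = [f.name for f in res.factors]
        if "const_cov" in names:
            assert res.factor("const_cov").contribution_abs == 0.0

    def test_uncorrelated_factor_contributes_nothing(self):
        """A covariate independent of wealth rank has Conc.I_k ~ 0 and a
        vanishing contribution even with a large OR."""
        rng = np.random.default_rng(21)
        n = 20000
        wealth = rng.normal(size=n)
        x = (rng.random(n) < 0.5).astype(float)  # strong driver, wealth-independent
        y = (rng.random(n) < expit(-1 + 2.0 * x + 0.5 * wealth)).astype(int)
        df = pd.DataFrame({
            "y": y, "x": x, "wealth": wealth, "w": np.ones(n),
            "psu": np.arange(n) % 50, "stratum": 0,
        })
        ds = hi.SurveyDataset(df, hi.ColumnConfig(
            weight_col="w", psu_col="psu", stratum_col="stratum", outcome_cols=["y"]
        ))
        res = hi.decompose_erreygers(ds, "y", ["x", "wealth"], rank_by="wealth")
        assert res.factor("x").or_ > 5.0
        assert abs(res.factor("x").factor_conc_i) < 0.02
        assert abs(res.factor("x").contribution_rel_pct) < 2.0

    def test_pro_poor_factor_gets_negative_contribution(self):
        """Positive marginal effect + concentration among the poor =>
        negative (inequality-reducing) contribution."""
        rng = np.random.default_rng(22)
        n = 20000
        wealth = rng.normal(size=n)
        x = (rng.random(n) < expit(-1.0 * wealth)).astype(float)  # poor-concentrated
        y = (rng.random(n) < expit(-1 + 1.5 * x + 0.8 * wealth)).astype(int)
        df = pd.DataFrame({
            "y": y, "x": x, "wealth": wealth, "w": np.ones(n),
            "psu": np.arange(n) % 50, "stratum": 0,
        })
        ds = hi.SurveyDataset(df, hi.ColumnConfig(
            weight_col="w", psu_col="psu", stratum_col="stratum", outcome_cols=["y"]
        ))
        res = hi.decompose_erreygers(ds, "y", ["x", "wealth"], rank_by="wealth")
        fx = res.factor("x")
        assert fx.coef > 0 and fx.factor_conc_i < 0
        assert fx.contribution_abs < 0

    def test_table_schema(self, decomposed):
        frame = decomposed.to_frame()
        assert {"factor", "OR", "elasticity", "conc_i",
                "contribution_abs", "contribution_rel_pct"} <= set(frame.columns)
        assert list(frame["factor"].iloc[-2:]) == ["residual", "total"]

    def test_elasticity_definition(self, decomposed, wealth_ds):
        f = decomposed.factor("urban")
        w = wealth_ds.weights
        xbar = np.average(wealth_ds.table["urban"], weights=w)
        fit = hi.fit_logit(wealth_ds, "outcome_utilisation", COVS)
        me = hi.marginal_effect(fit)
        assert f.elasticity == pytest.approx(me["urban"] * xbar / decomposed.mean_outcome)


class TestBootstrapContributions:
    def test_deterministic_and_sane(self, wealth_ds):
        a = hi.bootstrap_contributions(
            wealth_ds, "outcome_utilisation", COVS, n_reps=30, seed=5
        )
        b = hi.bootstrap_contributions(
            wealth_ds, "outcome_utilisation", COVS, n_reps=30, seed=5
        )
        assert a == b
        for lo, hi_ in a.values():
            assert lo <= hi_

    def test_interval_covers_wealth_contribution(self, wealth_ds, decomposed):
        cis = hi.bootstrap_contributions(
            wealth_ds, "outcome_utilisation", COVS, n_reps=60, seed=8
        )
        lo, hi_ = cis["wealth_score"]
        assert lo <= decomposed.factor("wealth_score").contribution_rel_pct <= hi_

    def test_attach_cis(self, wealth_ds, decomposed):
        cis = {f.name: (f.contribution_rel_pct - 1, f.contribution_rel_pct + 1)
               for f in decomposed.factors}
        res = hi.attach_bootstrap_cis(decomposed, cis)
        for f in res.factors:
            assert f.ci95_rel == cis[f.name]
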