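# Methods

## Model and estimands

The package measures socioeconomic inequality in a binary outcome
`y ∈ {0,1}` observed in a stratified two-stage cluster sample, ranked by a
continuous wealth score. The core quantities:

- **Fractional rank.** With weights `w_i` summing to `W`, and individuals
  ordered by the ranking variable, `r_i = (cum. weight of strictly
  lower-ranked + w_i/2)/W`. Ties share their block's midpoint rank. The
  weighted mean of `r` is exactly 0.5 — an algebraic identity the tests
  assert to 1e-12.
- **Concentration index.** `Conc.I = 2·cov_w(y, r)/ȳ` with the *population*
  weighted covariance (divide by total weight). The covariance form is used
  rather than the bare rank-sum `2/(n²ȳ)·Σ y_i r_i` because the latter is
  not mean-centred; the covariance form is what "the covariance between the
  outcome and the proportional wealth rank" denotes, and it equals the
  pairwise definition `Σ_i Σ_j w_i w_j (y_i−y_j)·sgn(x_i−x_j) / (2W²ȳ)`
  exactly — the test suite checks this equivalence to 1e-12 on grids of
  tiny weighted instances, including ties in the ranking variable.
- **Erreygers correction.** For bounded outcomes
  `E = (4ȳ/(y_max−y_min))·Conc.I`; the package restricts it to binary
  outcomes where `y_max−y_min = 1`, giving `E = 4ȳ·Conc.I`, range [−1,1],
  and the exact mirror property `E(1−y) = −E(y)`.
- **Wagstaff normalisation.** `Conc.I/(1−ȳ)`, the standard robustness
  companion for binary outcomes; undefined at `ȳ ∈ {0,1}`.
- A constant outcome returns index 0 with a warning rather than erroring,
  so pipeline runs over degenerate subgroups complete; a zero-mean outcome
  raises (the index divides by `ȳ`).

## Wealth index

PCA on the weighted correlation matrix of 0/1 asset indicators
(standardised by weighted means/SDs; population convention), scores being
the projection onto the leading eigenvector. Correlation rather than
covariance PCA is used because asset prevalences differ widely and the
correlation form is the common DHS practice. The eigenvector sign is fixed
by requiring positive weighted covariance between the score and the raw
asset count; a flip is recorded. Constant asset columns are dropped with a
warning (no information); an all-constant matrix raises. An optional
grouping column fits the PCA per group (country-specific indices) and
concatenates scores.

Quintiles: individuals sorted by (score, stable input order); each takes
the fifth containing its cumulative-weight midpoint (equivalently, cut
points at the weighted 20/40/60/80 percentiles). Tied-score blocks all
receive the label of the block's first member, making the label a
deterministic, monotone function of the score; with all scores tied
everything lands in Q1 with a mass-ties warning. With distinct scores each
quintile's weighted share is within half the largest single weight of 20%;
tie blocks can deviate further (they move as one unit).

## Decomposition

A weighted logistic regression (statsmodels GLM-Binomial with
`var_weights`; weights normalised to mean 1 so estimates *and* intervals
are invariant to weight rescaling) provides coefficients `β_k`. The
marginal effect is by default the average partial effect
`β_k^m = β_k · mean_w[p_i(1−p_i)]` (an effect-at-the-mean variant is
available; the choice is recorded in the result). The decomposition

`E = 4·Σ_k β_k^m x̄_k Conc.I_k + residual`

is evaluated per factor in the covariance form
`4·β_k^m·x̄_k·Conc.I_k = 8·β_k^m·cov_w(x_k, r)`, which is identical when
`x̄_k ≠ 0` and remains well defined for mean-centred covariates such as
the PCA score itself (whose own concentration index is then reported as
NaN). The residual is total `E` minus the sum of contributions, so
additivity holds to machine precision by construction; relative
contributions are percentages of `E` and sum to the explained share. A
factor with a positive marginal effect concentrated among the poor
(`Conc.I_k < 0`) gets a negative, inequality-reducing contribution.

Collinear columns are dropped (greedy rank check, logged) before fitting;
|coefficient| > 15 is treated as (quasi-)separation and raises with the
covariate named. Categorical covariates are expected as reference-coded
indicator columns, each decomposed separately.

## Uncertainty

The variance estimator behind published concentration-index intervals is
rarely stated; the package offers two and labels which was used:

- **analytic** — slope standard error of the convenient WLS regression of
  `2·var_w(r)/ȳ · y` on `r`, with PSU-clustered robust covariance;
- **bootstrap** (default 200 replicates) — PSUs resampled with replacement
  within strata, ranks and all statistics recomputed per replicate,
  percentile 95% intervals, deterministic under a seed. For decomposition
  contributions the entire chain (rank, logit fit, contributions) is
  re-run per replicate; replicates with non-convergent or separated fits
  are dropped and counted, and more than 20% dropped raises.

## Synthetic survey generator

The generator emulates the study conditions every downstream stage is
validated under:

- **Design.** Per stratum, a frame of 8× the sampled number of PSUs with
  household counts uniform on [max(80, 2·take), +150]; systematic PPS
  selection of PSUs (inclusion probability `n·M_j/M_total`, exact because
  no PSU exceeds the sampling interval); a fixed take of households per
  PSU; all eligible women per household (one by default,
  `1 + Poisson(mean−1)` otherwise). The stored weight is exactly
  `1/(p1·p2)` and both stage probabilities are kept as columns, so the
  design-consistency invariant is auditable row by row. Weights vary
  across strata (different frame totals), i.e. they are informative.
- **Wealth.** Latent household wealth `u_j + e_hj` with
  `u_j ~ N(0, ρ)`, `e ~ N(0, 1−ρ)`: standard normal overall with
  intracluster correlation exactly ρ. Normality is a modelling choice made
  for analytic ICC control, not an empirical claim.
- **Assets.** Asset k owned with probability `logistic(a_k + b_k·wealth)`,
  `a_k ~ U[−1.5, 1.5]`, `b_k ~ U[0.5, 2.0]` by seeded draw (overridable):
  all slopes positive, so the first principal component is recoverable.
- **Covariates.** Age (uniform 15–49), schooling (`N(6+2·wealth, 3)`
  rounded, clipped to [0,18]), urban / media exposure / insurance
  (logistic in wealth), household size, marital and employment status
  (wealth-independent). The wealth-linked covariates create realistic
  confounding; the wealth-independent ones serve as true nulls in recovery
  studies.
- **Outcomes.** Bernoulli with logit-linear predictors on covariates and
  latent wealth, user-set. The shipped defaults target pooled prevalences
  of roughly 37% (knowledge) and 29% (utilisation) with a pro-rich
  gradient, matching the magnitudes the pipeline is meant to operate at.

What the generator does **not** emulate: non-response/missingness,
self-weighting designs, country heterogeneity in asset baskets, spatial
structure, or measurement error in self-reports. Passing tests therefore
demonstrate correctness of the estimators under a clean two-stage design
with known truth — not robustness to those real-data features.

## Validation choices and problem sizes

- Index axioms (bounds, mirror, Erreygers identity, weight/rank scale
  invariance, sign condition) are asserted exactly (1e-12) on a grid of
  100 generated surveys spanning ICC 0.1–0.74.
- Single-driver recovery: outcome driven by latent wealth alone
  (coefficient 0.8), n = 50,000 (2 strata × 100 PSUs × 250 households),
  20 seeds; the full pipeline (PCA score → rank → fit → decomposition) must
  put the wealth factor's relative contribution within 2 points of the
  explained share and every wealth-independent factor within ±2 points of
  zero. The ~3% unexplained share is the logit's nonlinearity (the
  decomposition is linear in the ranks), not estimation error.
- ICC recovery uses the one-way ANOVA estimator at the 50-PSU × 20-woman
  design. A single dataset of that size has an estimator SE of ≈0.05, so
  the check is run as the mean over replicate datasets (10 in the tests,
  20 in the acceptance script), a Monte-Carlo estimate under the same
  design with SE ≈0.012.
- Bootstrap coverage of contribution intervals is exercised as a
  single-seed covers-the-point check plus determinism; a full coverage
  study was deliberately left out of the default suite for runtime, the
  interval machinery being identical to the SE machinery that is checked.
- Gap-table reproduction: the published poorest/richest utilisation
  prevalences (pooled 18-country estimate plus 23 high-income-country
  studies) are shipped with the package; RPD, RPR and relative gap are
  recomputed from Q1/Q5 and compared to print under round-half-away-from-
  zero at 2 decimals — all 72 derived cells match. The printed
  concentration indices in that table are primary data, not derivable from
  Q1/Q5, and are carried for reference only.

## Known limitations

- The chi-square crosstab treats normalised weights as frequencies with no
  design adjustment (no Rao–Scott correction); with strong clustering its
  p-values are anti-conservative.
- The decomposition inherits the usual caveats of regression-based
  inequality decomposition: it is an accounting identity over a fitted
  model, not a causal attribution, and the residual absorbs both
  approximation error of the linearisation and omitted factors.
- The Erreygers/Wagstaff corrections are implemented for binary outcomes
  only; fractional or count outcomes are out of scope.
- Pooled headline estimates of the motivating application (e.g. a pooled
  Conc.I near 0.3 for screening utilisation across 1.8M women) require the
  restricted microdata and are not reproduced; the package validates the
  estimators, not those numbers.
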