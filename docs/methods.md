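# Methods

## The state-space model

The core estimator is a dynamic factor analysis for short multivariate annual
time series: n observed series are explained by m ≪ n shared latent trends
that evolve as independent random walks,

    x_t = x_{t-1} + w_t,   w_t ~ N(0, Q)
    y_t = Z x_t + v_t,     v_t ~ N(0, R)

with t = 1..T annual steps. Three fixings make the model estimable and set
the scale of the latent process:

* **Q = I.** The process covariance is fixed to the identity; trend scale is
  absorbed into the loadings Z.
* **x₀ = 0 with zero variance.** Observed series are z-scored (mean 0,
  sd 1, denominator n−1) before fitting, so anchoring the trends at zero is
  consistent with the data scale. A diffuse initialization would also work
  but is not the default; with T ≈ 20 the anchoring choice is visible mainly
  in the first one or two smoothed states.
* **R diagonal**, either one shared variance (`diagonal_equal`, 1 free
  parameter) or one per series (`diagonal_unequal`, n parameters).

Rotational indeterminacy during estimation is removed by the standard
constraint that entries above the diagonal in the first m rows of Z are zero
(z_ij = 0 for j > i, i ≤ m). Free parameter count is therefore
k = nm − m(m−1)/2 plus 1 or n for R, and AIC = −2·logL + 2k exactly.

### Likelihood and EM

The log-likelihood comes from the prediction-error decomposition of a Kalman
filter. Because R is diagonal, the measurement update is done in information
form, P_filt = (P_pred⁻¹ + Z′R⁻¹Z)⁻¹, with the matching Woodbury identities
for |F| and the innovation quadratic form; all n-dimensional contractions
(Z′R⁻¹y_t, y_t′R⁻¹y_t, Z′R⁻¹Z) are precomputed once per likelihood
evaluation, so each time step costs O(m²) rather than O(n³). This is exact,
not an approximation, and is verified against a brute-force oracle that
evaluates the density of the stacked nT-vector under
Cov(y_t, y_s) = Z·min(t,s)·Z′ + δ_ts·R (agreement to ~1e−13 on random small
instances; the test bound is 1e−8).

EM alternates the fixed-interval (RTS) smoother (E-step) with closed-form
updates of Z and R (M-step). With Q and x₀ fixed only the smoothed first and
second moments of x_t are needed — no lag-one covariances. Z rows update by
restricted least squares on their free entries; R from the expected squared
residuals (averaged across series for `diagonal_equal`). Both steps are
exact joint minimizers, so the log-likelihood is non-decreasing; this is
asserted at every iteration with a 1e−9 floating-point allowance, and the
test suite checks traces at 1e−10. Iteration stops when the improvement
falls below `tol` (default 1e−6 absolute) or at `max_iter` (default 2000);
non-convergence returns the fit with `converged=False` and a warning. EM for
factor models plateaus slowly, so long single-trend fits routinely end by
`max_iter` with the trend correlation already > 0.999 — the smoothed states
stabilize far earlier than the last decimals of the likelihood.

Initialization is deterministic (no seed plumbing): Z from the first m
principal directions of the data covariance (unit norm, constrained entries
zeroed, a fixed sign convention for reproducibility across LAPACK builds),
R at half the mean data variance.

### Model selection and reporting

Candidates are the cross of trend counts (default {1, 2}) and the two R
structures; minimum AIC wins, ties (within 1e−9) break toward fewer
parameters. AIC is computed on the unrotated fit. For reporting, m ≥ 2
solutions are varimax-rotated (statsmodels' rotation, applied as Z → ZH,
x → H′x, which leaves the likelihood invariant because the random-walk prior
is isotropic), and each trend is sign-flipped so its loading sum is
non-negative.

## Portfolio metrics

* **Diversity** is the reciprocal Simpson index 1/D, D = Σ pᵢ², over revenue
  shares by fishery (taxon × location, gear aggregated). The window-level
  value is the weighted mean of annual indices with each year weighted by
  its revenue share. The sentence defining the weighting admits a second
  reading — 1/D of shares pooled over the window — so both are computed
  (`weighted_reciprocal`, `pooled_reciprocal`); the weighted mean is the
  default used downstream.
* **Turnover** is Jaccard dissimilarity between pre- and post-period catch
  compositions aligned on the union fishery set. On proportion data the
  abundance-based (Ružička) form 1 − Σmin/Σmax is the default; a binary
  presence/absence variant sits behind `variant="binary"`. The quantitative
  form is the one consistent with a continuous 0–0.4 turnover range on real
  landings compositions.
* Conventions: diversity uses revenue shares, turnover uses catch (pounds)
  shares; the regime year (1989) belongs to the **pre** window
  (pre = 1980–1989, post = 1990–1999); zeros in landings are true zeros, not
  missing; communities must have positive revenue in every window year to
  enter the analysis, stocks may have at most 3 zero-catch years.

## Regressions

Percent change in mean annual real revenue, 100·(mean_post −
mean_pre)/mean_pre, is regressed (OLS, statsmodels) on log diversity, and on
diversity + turnover + diversity:turnover with raw covariates by default
(`log_covariates` transforms both, with ε = half the smallest positive
turnover guarding log 0). Standardized effects come from refitting on
z-scored covariates with the interaction as the product of z-scores.
p-values are two-sided t-tests without multiple-testing correction (two
pre-specified models). Degenerate designs degrade explicitly: constant
turnover drops to a diversity-only model with a warning; a scalar
(statewide) price change reduces the catch/price/product regression to the
catch term, since a constant regressor is collinear with the intercept.

## The synthetic scenario

`gen_regime_scenario` emulates the study system: ~105 communities holding
revenue shares across ~60 fisheries over 1980–1999.

* **Catches**: fishery catch = base · exp(z_f · x_t) with shared latent
  random-walk trends x_t (process sd 1) receiving a N(0, trend_step_sd²)
  level shift after the regime year (default sd 2 — a clearly visible step),
  and fishery loadings z_f ~ N(0, 0.08²). The exponential link keeps
  landings positive (the estimator works on z-scores; the link is purely a
  generator choice). The loading scale was set so per-community revenue
  changes span roughly −80…+150%, a realistic spread for two-decade
  community revenues; larger values produce thousand-percent outliers no
  real community shows.
* **Prices**: lognormal base prices around $1/lb with 5% annual noise; a
  designated salmon-like subset (30% of fisheries) has prices multiplied by
  `price_drop_factor` (default 0.5) after the regime year, mirroring the
  aquaculture-driven collapse of salmon ex-vessel prices.
* **Portfolios**: community shares are Dirichlet draws whose concentration
  sweeps log-spaced from 0.02 (single-fishery specialists) to 100
  (near-even generalists, reciprocal Simpson ≈ fishery count). Specialist
  communities' Dirichlet base weights are biased toward the salmon-like
  fisheries (16× at the specialist end, 1× at the generalist end),
  reflecting the geography of remote, salmon-dependent villages. This
  coupling is what converts the price shock into a *mean* gradient of
  revenue response against diversity; with unbiased portfolios,
  diversification would only reduce the variance of the response, not its
  expectation.
* **CPI**: 3% annual inflation anchored at a 2013 base; nominal revenues
  are inflated real ones, so the ingest deflation round-trips exactly.
* The ecosystem shift (trend step) and market shift (price drop) are
  independently switchable; setting both to null gives a no-signal scenario
  whose mean revenue change is statistically indistinguishable from zero.

What the generator does **not** emulate: real species lists and geography,
confidentiality suppression of small fisheries, permit migration between
communities, serially correlated price shocks, or observation error in
landings. Passing tests therefore demonstrate estimator correctness and the
qualitative mechanism, not calibration to Alaskan magnitudes.

## Problem sizes and numerical choices

Validation studies run at: 100 random instances (n ≤ 4, T ≤ 6, m ≤ 2) for
oracle agreement; 20 replicates of n=20, T=200, obs sd 0.3 for single-trend
recovery (|corr| ≥ 0.95 required in ≥ 18); 25 replicates of a two-block
two-trend design (n=12, T=40) for AIC selection (≥ 80% correct required);
20 replicates of the full designed scenario for the regression gradient.
These sizes give stable pass/fail behaviour at a few minutes of total
compute on one CPU.

Other numerics: observation variances are floored at 1e−10; constant series
are a fatal error before z-scoring (they carry no trend information);
correlation of a zero-variance series is fatal rather than NaN; summary
floats are serialized at 12 significant digits; the run-config hash excludes
the output directory and log level so reruns of the same analysis hash
identically.

## Known limitations

* Missing values in panels are not supported (the completeness filters
  guarantee dense panels); a missing-data EM would be the natural extension.
* State dynamics are pure random walks; no autoregressive or covariate
  terms inside the state-space model.
* The catch/price/product supplementary regression is implemented
  generically (per-community percent changes, OLS with product term); finer
  specifications (log changes, aggregate fits) are possible but not built
  in.
* Figure regeneration is deterministic in content given fixed library
  versions, but PNG bytes embed library metadata and are not guaranteed
  byte-identical across environments.
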