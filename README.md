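# fishfolio

Tools for asking how **portfolio diversity** and **compositional turnover**
buffer the fishing revenues of resource-dependent communities against abrupt
ecosystem and market regime shifts — the kind of question raised by the 1989
North Pacific oceanographic shift and the concurrent collapse of salmon
ex-vessel prices, which hit Alaskan fishing communities very unevenly.

The package ingests long-format community landings records (community × year
× fishery, with pounds landed and nominal ex-vessel revenue, in the style of
the Alaska CFEC community earnings files), deflates revenues with an annual
CPI table, and then runs four analysis stages:

1. **Dynamic factor analysis (DFA).** Shared latent trends in *n* z-scored
   annual series (stock catches, or community revenues) are extracted with a
   multivariate random-walk state-space model

   ```
   x_t = x_{t-1} + w_t,   w_t ~ N(0, Q),  Q = I  (fixed)
   y_t = Z x_t + v_t,     v_t ~ N(0, R),  R diagonal
   ```

   fitted by maximum likelihood (Kalman smoother + EM), with the number of
   trends m ∈ {1, 2} and the R structure (one shared variance vs one per
   series) chosen by AIC = −2·logL + 2k. Varimax rotation and a
   positive-loading-sum sign convention are applied for reporting.

2. **Portfolio diversity.** Per community, the reciprocal Simpson index
   1/D = 1/Σᵢ pᵢ² of revenue shares pᵢ across fisheries (taxon × location),
   computed annually over the pre-shift decade and averaged with each year
   weighted by its share of total revenue. 1/D is the effective number of
   fisheries: 1 for a specialist, k for an even k-way split.

3. **Turnover.** Jaccard dissimilarity between each community's pre- and
   post-shift catch compositions, in the abundance-based (Ružička) form
   J = 1 − Σ min(Aᵢ, Bᵢ) / Σ max(Aᵢ, Bᵢ).

4. **Regime-response regressions.** Percent change in mean annual real
   revenue from the pre decade (1980–1989) to the post decade (1990–1999),
   regressed on log diversity, and on diversity × turnover with an
   interaction, with standardized effect sizes from z-scored covariates.

A seeded synthetic-scenario generator (`fishfolio.simulate`) produces
CFEC-like landings with known latent trends, a regime step, a salmon price
collapse and a specialist→generalist diversity gradient, so the entire chain
runs — and can be validated against ground truth — without any external data.

## Worked example

```python
import fishfolio as ff

# a synthetic study system: 105 communities, 60 fisheries, 1980-1999,
# regime shift after 1989 with a 50% salmon price drop
cfg = ff.ScenarioConfig(seed=1)
records, catch_panel, truth = ff.gen_regime_scenario(cfg)

# shared trend in stock catches
z = ff.zscore(catch_panel)
best, table = ff.select_model(z, [ff.DFAModelSpec(m=1), ff.DFAModelSpec(m=2)])
print(best.m, round(best.aic, 1))

# diversity-resilience gradient
resp = ff.build_responses(records, range(1980, 1990), range(1990, 2000))
fit = ff.fit_loglinear(resp)
print(round(fit.coefficients["log_diversity"], 2),
      f'{fit.p_values["log_diversity"]:.2g}', round(fit.r_squared, 3))
```

prints (seed 1):

```
2 -12148.1
7.67 1.3e-09 0.302
```

i.e. AIC prefers two shared catch trends for this draw, and the percent
revenue change increases by ≈ 7.7 points per log-unit of diversity — more
diversified communities lost significantly less revenue across the simulated
regime shift (p ≈ 10⁻⁹, R² ≈ 0.30 across 105 communities).

The same pipeline runs from the shell:

```bash
fishfolio simulate --seed 1 --out scenario/
fishfolio run-all --config run.yaml     # ingest -> DFA -> metrics -> regressions
fishfolio figures --run-dir out/        # re-render plots from the saved CSVs
```

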