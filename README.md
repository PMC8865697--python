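# gdpmort

Estimation of excess under-5 deaths attributable to economic downturns:
country-specific log-log mixed-effects elasticities of the under-5 mortality
rate (U5MR) with respect to GDP per capita, counterfactual projection under
5/10/15% GDP-per-capita reductions, lives-lost accounting, and Monte Carlo
uncertainty propagation. A synthetic-panel generator with known ground truth
makes the whole pipeline testable offline.

## Pipeline

1. **panel_data** (`gdpmort.panel`) — country-year panel container, long/wide
   CSV readers, validation, LMIC filter (GNI per capita strictly below
   12,375 US$, or a low / lower-middle / upper-middle label when GNI is
   absent), and per-variable summary tables (mean, SD, % missing).
2. **imputation** (`gdpmort.impute`) — GDP completed with a trailing
   five-year moving average (filled left-to-right, so later fills may use
   earlier imputed values; leading gaps back-filled from the earliest window);
   covariates completed by iterative chained linear-Gaussian regression on
   the other covariates plus log GDP and year (deterministic conditional
   means by default; `stochastic=True` adds residual-scale noise).
3. **elasticity_model** (`gdpmort.elasticity`) — REML mixed model of
   log U5MR on log GDP with a per-country random intercept and slope
   (independent components by default; `correlated_re=True` for the full
   2×2 structure with automatic boundary fallback). Model 1 is GDP-only;
   Model 2 adds electric power, women-in-parliament share, total fertility,
   physicians per 1,000, DPT coverage, and region/income-group fixed
   effects. Per-country elasticity = fixed slope + BLUP deviation; its
   standard error is the Kackar–Harville prediction-error SE
   `sqrt(u'Au + condvar)`, combining fixed-effect uncertainty (adjusted for
   its correlation with the BLUP) with the BLUP's conditional variance.
   Noise-free panels short-circuit to the exact saturated per-country OLS
   solution.
4. **scenario_projection** (`gdpmort.scenarios`) — scenario U5MR is
   `exp(alpha_j + covariate terms + beta_j * ln((1-r) * gdp_2019))` (naive
   retransformation, no smearing), deaths = U5MR × under-5 population / 1000.
   Note the deliberate convention: deaths are weighted by the **under-5
   population**, not live births. Additional deaths are scenario minus
   baseline (r = 0) from the same fit, so
   `deaths(r)/deaths(0) = (1-r)^beta_j` holds exactly. 95% bounds are
   log-symmetric: `exp(log prediction ± 1.96 · s_pred)` with
   `s_pred² = x'C_j x + sigma²` (C_j the BLUP conditional covariance).
5. **monte_carlo** (`gdpmort.montecarlo`) — per iteration, each country's
   slope is drawn from `Normal(beta_j, se_j²)` (intercepts and covariate
   coefficients fixed); totals are summarized by mean, SD (n−1), and
   percentile 95% intervals. Per-country substreams are derived from the
   root seed and the country id, so results are invariant to country order.
6. **synthetic_data** (`gdpmort.synthetic`) — simulates WDI-style panels:
   lognormal GDP paths (annual log-shock SD 0.10 by default, chosen so
   31-year series identify country slopes), covariates with mild log-GDP
   dependence, log-log mortality with country-varying elasticities
   (mean −0.2845), configurable per-variable/per-year missingness (MCAR by
   default, optional GDP-dependent MAR), GNI classification values and
   under-5 populations. Returns the panel plus its generating ground truth.
7. **reporting_cli** (`gdpmort.reporting`, `gdpmort.cli`) — regional /
   income-group / global aggregation, shares of additional deaths,
   percent-increase-above-baseline, top-N country tables, and CSV rendering
   (deaths rounded half-up to integers, percentages to one decimal, at
   render time only).

## CLI

```bash
gdpmort simulate --seed 42 --out panel.csv --truth truth.json
gdpmort impute   --panel panel.csv --out imputed.csv --report imp.json
gdpmort fit      --panel imputed.csv --model 2 --out fit.json
gdpmort project  --fit fit.json --panel imputed.csv \
                 --reductions 0.05,0.10,0.15 --out scenarios.csv
gdpmort mc       --fit fit.json --panel imputed.csv --iters 500 \
                 --seed 20200901 --out mc.json
gdpmort report   --fit fit.json --panel imputed.csv --by region --out-dir out/
```

`simulate` accepts a YAML/JSON config (`--config sim.yaml`) mirroring
`GeneratorConfig` fields.

## Panel CSV dialect

UTF-8, comma-separated, header required. Canonical long columns:
`country_id, year, u5mr, gdp_pc, electric_power_kwh_pc,
women_parliament_pct, total_fertility, physicians_per_1000,
dpt_coverage_pct, under5_pop, gni_pc, region, income_group`.
Missing numeric cells are empty or `NA` (never 0). A wide layout
(`country_id, variable, 1990, 1991, ...`) is accepted on read.

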