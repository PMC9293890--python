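# panelits

Segmented interrupted-time-series analysis of provincial daily search-index
panels, implemented as a reusable Python package:

- **`panelits.simulate`** — generator of synthetic daily search-index panels
  from a log-normal model with province random intercepts/slopes, AR(1)
  residuals, month/day-of-week cycles and five step/slope exposures whose
  magnitudes differ by development stratum. Ground truth is recorded for
  recovery studies; published point estimates ship as defaults.
- **`panelits.io`** — validated CSV/YAML reading and writing for panels
  (`province,date,index`), province metadata, exposure schedules, results.
- **`panelits.design`** — design-matrix construction: day clock `T`,
  persistent step indicators, post-peak slope clocks, seasonal dummies
  (January / Friday reference), stratum interactions or a standardized
  continuous covariate, plus the per-province random-effect design.
- **`panelits.lmm`** — maximum-likelihood (or REML) fitting of the linear
  mixed model with province random intercept+slope and AR(1) within-province
  residual correlation. Likelihood evaluations are O(n) per province via
  AR(1) whitening and the Woodbury identity; beta is profiled by GLS.
  AIC/BIC and residual diagnostics included.
- **`panelits.effects`** — level-change RRs, time-rescaled slope RRs
  (week/month/year), ratio-of-RR contrasts between strata or per SD of a
  continuous covariate, Wald intervals, Holm–Bonferroni decisions, and a
  full effects table with Markdown rendering.
- **`panelits.descriptives`** — pre/post medians, IQRs and crude relative
  change per province plus the national (province-summed) series.
- **`panelits.cli`** — `panelits` command with `simulate`, `descriptives`,
  `fit`, `report` and `recover` subcommands; deterministic under a fixed
  seed.

## CLI quick start

```sh
# synthetic panel with the published coefficients as ground truth
panelits simulate --seed 7 --provinces-per-category 3 --out-dir out/sim

# end-to-end analysis: descriptives, AR(1) LMM fit, effects table
panelits report --panel out/sim/panel.csv --meta out/sim/metadata.csv \
    --out-dir out/report

# simulate-and-refit recovery study
panelits recover --replicates 5 --seed 1 --out-dir out/recovery
```

`report` writes `descriptives.csv/.md`, `coefficients.csv`, `effects.csv/.md`,
`fit.json` and `run.log`. Continuous covariate analyses use
`--hdi-mode continuous:hdi` (or `continuous:gnppp`, `continuous:education`,
`continuous:life_expectancy`).

## Conventions

- Index values must be strictly positive (the model is on `ln(index)`);
  zeros are rejected, not offset.
- Step indicators persist once switched on; slope clocks are 0 on their
  start date and count days thereafter. Slope RRs are reported per week by
  default (x7 days), trends per year (x365).
- AR(1) correlation across missing days decays as `rho ** gap`.
- ML is the default estimation method so AIC/BIC comparisons across
  fixed-effect structures are valid; REML is available via `--method reml`.
- The continuous metadata columns produced by the default metadata are
  documented placeholders, not real indicator values; supply your own
  metadata CSV for real analyses.
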