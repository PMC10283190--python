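# vaxcount

Bayesian multilevel count models for childhood vaccine-uptake data.

Counts of vaccine doses received by children in household surveys are
awkward for ordinary Poisson regression: the variance far exceeds the
mean, and far more children have *zero* doses than any Poisson model
allows. `vaxcount` implements the standard model-comparison workflow for
such data — four count families fitted as three-level hierarchical
Bayesian regressions and ranked by predictive information criteria —
together with a calibrated synthetic-data generator, so the entire
analysis is reproducible without access to restricted survey microdata.

## The models

For child *i* in community *j* in state *k*, with covariates
*x*, the outcome is the number of doses *y* ∈ {0, …, 9}:

- **Poisson**: y ~ Poisson(μ), equidispersed (Var = μ);
- **NB**: y ~ NB(μ, k) with Var = μ + μ²/k — overdispersion via the
  dispersion parameter k (k → ∞ recovers the Poisson);
- **ZIP / ZINB**: a structural-zero mixture,
  P(y=0) = π + (1−π)·P₀(0), P(y≥1) = (1−π)·P₀(y), with base P₀ Poisson
  or NB and logit-linear π.

Each family's mean is modelled on the log scale with exchangeable
Gaussian random effects at two grouping levels:

    log μ_ijk = x_ijk'β + u_j + v_k,   u_j ~ N(0, σ²_community),  v_k ~ N(0, σ²_state)

Priors are weakly informative and centred on crude data summaries
(intercept at the log weighted mean outcome; zero-part intercept at the
logit of the observed zero excess). Posteriors are drawn by an adaptive
Metropolis-within-Gibbs sampler (fixed effects in joint blocks,
random-effect vectors by vectorised single-site updates, scale
parameters on the log scale); the default configuration is 4 chains of
15,000 iterations (half warmup) thinned by 50. Fitted families are
compared by −2 Log LL (deviance at the posterior mean), WAIC, and
PSIS-LOO (LOOIC), all computed from the pointwise log-likelihood matrix;
the lowest LOOIC wins, with WAIC concordance reported.

## Worked example

```bash
python analysis/01_simulate.py 1      # survey-like synthetic data, n ~ 10^4
python analysis/02_descriptives.py    # weighted summaries + dispersion check
python analysis/03_fit_models.py 1    # fit all four families (few minutes)
python analysis/04_report.py          # comparison table + variance partitioning
```

The first two steps print:

```
simulated 9990 children in 370 communities across 37 states (seed 1)
outcome: mean 4.30, variance 12.77, 28.4% zeros, 19.4% folded at the 9-dose cap

         mean  median  variance  zero_fraction
2003     3.74     3.0     10.91           0.29
2008     4.03     4.0     12.06           0.29
2013     4.60     5.0     13.39           0.28
2018     4.84     5.0     13.96           0.28
overall  4.30     4.0     12.77           0.28

mean 4.30, variance 12.77 (ratio 2.97); variance exceeds the mean: Poisson
equidispersion is violated; zero fraction 0.284 exceeds the Poisson-implied 0.014
```

The generator is moment-matched to the pooled-survey targets (overall
mean 4.36, variance 12.82, median 4), rises in uptake across survey
years, and shows the two features that drive the modelling choice: a
variance/mean ratio near 3 (overdispersion) and a zero fraction ~20×
the Poisson-implied mass (excess zeros). Step 03 then fits the four
families and step 04 prints the ranking — on ZINB-generated data the
ZINB fit attains the lowest LOOIC and WAIC, with Poisson worst, the same
ordering reported for the real pooled surveys.

As a library:

```python
from vaxcount import (ModelSpec, SamplerConfig, fit_ic, run_mcmc,
                      scaled_presets, simulate_dataset)

design, truth = scaled_presets("desk")          # 2,000 children, ZINB truth
data = simulate_dataset(design, truth, seed=7)
spec = ModelSpec(family="zinb", count_formula=tuple(data.covariate_names))
draws = run_mcmc(data, spec, config=SamplerConfig(
    iterations=3000, warmup=1500, thin=3, chains=2, seed=11))
print(fit_ic(draws, data, spec).summary())
```

## Layout

- `src/vaxcount/` — the library: `families` (pmfs, moments, sampling),
  `simulate` (hierarchical generator + presets), `model` (design
  matrices, likelihood, priors), `mcmc` (sampler, diagnostics),
  `selection` (WAIC, PSIS-LOO, deviance, comparison), `descriptives`
  (survey weights, weighted summaries, VPC), `pipeline` (end-to-end
  runner).
- `analysis/` — the numbered drivers above.
- `docs/methods.md` — modelling assumptions, calibration, and numerical
  choices.
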