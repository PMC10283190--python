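# Methods

## Outcome and model family

The outcome is a bounded count: the number of vaccine doses (0–9) a
child has received, pooled across four survey rounds. Four generative
families are fitted: Poisson, negative binomial (NB), and their
zero-inflated mixtures (ZIP, ZINB). A single parameterisation is used
throughout: mean `mu`, NB dispersion `k` with `Var = mu + mu^2/k`
(`k -> inf` recovers the Poisson), and structural-zero probability
`pi` in `[0, 1)` entering as `P(0) = pi + (1-pi) P0(0)`,
`P(y>=1) = (1-pi) P0(y)`. `pi = 1` (an all-zero model) is rejected as
degenerate. Two printed variants of these pmfs circulate — a zero-
truncated ("hurdle-like") ZIP zero branch, and an inverse-dispersion
ZINB convention — but only the mixture form above sums to one under a
common `k`, so it is the one implemented; the reductions
`ZIP(pi=0) = Poisson` and `ZINB(pi=0) = NB` hold exactly.

All pmfs are computed through log-gamma functions. For `k > 1e6` the
log Gamma(k+y) − log Gamma(k) difference is replaced by its asymptotic
expansion `y log k + y(y-1)/(2k) − y(y-1)(2y-1)/(12k^2)`, because the
direct difference of two O(k log k) values carries ~k·eps of float
noise, which at k ≥ 1e8 would exceed the true NB–Poisson gap
(`(y(y-1)/2 − y mu + mu^2/2)/k` to leading order).

## Hierarchical structure

Children (level 1) nest in communities (level 2) nest in states
(level 3). The log-mean is `x'beta + u_comm + u_state` with
exchangeable Gaussian random effects (no spatial structure). The zero
part is intercept-only by default — the mixture weight is a single
scalar on the logit scale — with optional covariates and optional
zero-part random effects (`r` vectors); these are off by default
because the data this emulates never supported zero-part group
estimates. Categorical covariates are reference-coded with the first
listed level as reference (survey year: first round = reference).

## Priors

"Weakly informative, derived from the data" is made concrete as:
intercept ~ N(log weighted-mean(y), 1.5); other coefficients ~ N(0, 1);
sigma_community, sigma_state ~ half-Normal(1); log k ~ N(0, 1.5);
zero-part intercept ~ N(logit(observed zero excess), 1.5), where the
zero excess is the observed zero fraction minus the Poisson-implied
`e^{-mean}` (floored at 0.02). These centres and scales are package
conventions, configurable through `PriorConfig`.

## Sampling

The built-in sampler is adaptive Metropolis-within-Gibbs:

- `beta` and (for ZI families) `gamma` as joint random-walk blocks, the
  proposal covariance adapted from the warmup history
  (2.38²/d scaling, target acceptance 0.234);
- each random-effect vector by *vectorised single-site* proposals: all
  groups propose simultaneously and accept independently, valid because
  a group's conditional depends only on its own rows (per-group
  log-likelihood sums via bincount), target acceptance 0.44 per site;
- `log sigma` updates involve only the prior terms (the likelihood
  depends on sigma only through u), with the Jacobian `+log sigma`
  included; `log k` is a scalar random walk with its Normal prior
  applied directly on the log scale.

Adaptation runs only during warmup (Robbins–Monro, step `t^-0.6`), so
the post-warmup kernel is fixed. Initial values: `beta` from least
squares of `log(y+0.5)` on X, sigmas at 0.1, k at 1, zero-intercept at
the prior centre, with small jitter per chain; non-finite starts are
re-drawn up to 20 times. Defaults mirror the source configuration
(15,000 iterations per chain including warmup, 4 chains, thinning 50);
warmup is set to half the iterations as a convention, and thinning is
kept as a faithful default although it discards information. Chains run
sequentially from seeds spawned off one `SeedSequence`, so every run is
exactly reproducible. Linear predictors are clipped at ±30 inside the
sampler before exponentiation/expit — far outside any region of
posterior mass — purely to keep proposals finite.

Convergence is summarised by rank-normalised split R-hat and bulk ESS
(via arviz), flagging R-hat > 1.01 or ESS < 400; constant parameters
are reported as degenerate rather than erroring, and R-hat is omitted
for single-chain runs.

## Model comparison

The pointwise log-likelihood is **conditional on the random effects**
(the convention of the multilevel-regression software this mirrors);
marginalised LOO would need per-observation integration. From the
(draws × observations) matrix:

- **WAIC** = −2 Σᵢ (lppdᵢ − pᵢ), lppdᵢ by log-sum-exp,
  pᵢ = Var_draws(llᵢ); SE = 2·sqrt(n·Var_i of pointwise contributions).
- **PSIS-LOO**: importance ratios 1/p(yᵢ|θ_s), the largest 20% (min 5)
  smoothed by a generalized-Pareto fit using the quantile-anchored
  profile-posterior estimator (candidate slopes anchored at the first
  quartile, profile-likelihood weights, shape regularised toward 0.5
  with ~10 pseudo-observations); smoothed weights are capped at the raw
  maximum; the per-observation shape k-hat is reported and > 0.7
  flagged. A zero-variance likelihood column has nothing to smooth and
  returns elpd = lppd exactly.
- **−2 Log LL** is ambiguous in common use; both readings are computed:
  deviance at the posterior mean of *all* parameters (random effects
  included) — the headline value — and the posterior mean deviance.

Families are ranked by LOOIC ascending; ties break by WAIC, then by
fewer effective parameters. The winner is the lowest LOOIC, with WAIC
concordance noted.

## Survey weights

The analysis weight is (provided weight / documentation divisor) × SSW,
where SSW = sampled women / population women for the survey round.
Weights enter **only** the descriptive summaries (frequency-weight
convention: duplicating a row ≡ doubling its weight; unit weights
reproduce unweighted formulas exactly). Likelihoods are unweighted: the
fits emulate an analysis that reported unweighted multilevel estimates,
and weighted multilevel pseudo-likelihood is a different estimator,
deliberately out of scope.

The overdispersion flag allows 2 sampling-SDs (`2·sqrt(2/n_eff)`) above
ratio 1 so an equidispersed sample is not flagged on noise.

## Variance partitioning

No standard VPC definition exists for these models, so the reported
coefficients are a documented convention on the latent (log-mean)
scale: per draw, `VPC_level = sigma_level² / (sigma_comm² +
sigma_state² + V1)` with level-1 term `V1 = 1/exp(eta-bar)` (the
log-normal–Poisson approximation at the mean linear predictor), plus
`1/k` for NB-type families and `pi²/3` when zero-part random effects
are modelled; shares including V1 sum to one per draw. Published VPC
values computed under an unprinted definition are not expected to be
recoverable from this convention.

## Synthetic data

The generator replaces restricted survey microdata. It draws the
three-level hierarchy, categorical covariates at their proper level
(child / community / state; community-level covariates constant within
community), Gaussian random effects, and outcomes from the chosen
family, then right-truncates at `max_count` (default 9) and logs the
truncated fraction. Covariate marginal distributions are conventions
(roughly survey-plausible frequencies; uniform where nothing is known),
not facts about any real dataset.

Presets:

- `tiny` (3×2×10 = 60) and `desk` (10×5×40 = 2,000) for tests and
  replication; the desk truth is ZINB with pi = 0.25, k = 1.5,
  sigma_comm = 0.20, sigma_state = 0.15 and nine fixed effects of
  survey-realistic magnitude. The desk cap is 30 rather than 9 so the
  recovery benchmark stays inside the fitted (untruncated) family.
- `full`: 37 states, 1,338 communities, ~12,760 children — the pooled-
  survey scale.
- `dhs-like`: ~10^4 children, 37 states. Its ZINB truth (intercept
  1.754, k = 3, pi = 0.260, year effects following the observed upward
  trend, sigma_comm = 0.07, sigma_state = 0.13) is moment-matched (see
  `_calibration.py`) so the capped-at-9 marginal outcome has mean 4.36,
  variance 12.82 and median 4. Two consequences are intentional: the
  zero fraction comes out ≈ 0.28 (a mean of 4.36 with variance 12.82 on
  support [0, 9] *forces* a large zero spike), and ≈ 20% of latent
  counts fold onto the cap — which is precisely the real-world pile-up
  of fully vaccinated children at the maximum dose count, not an
  artefact to minimise.

What passing tests on these data do **not** show: robustness to
informative sampling weights in the likelihood, to non-exchangeable
(spatial) clustering, to covariate measurement error, or to the
recall/card-availability artefacts of real immunisation data.

## Problem sizes and tolerances in the test suite

Recovery and selection checks run at desk scale: 20 replicates for
credible-interval coverage of the nine fixed effects (binomial 3-sigma
band around 0.95), 10 replicates for ZINB selection recovery plus 3
equidispersed null replicates, each fit using short adaptive chains
(1,600–2,400 iterations, single chain) — enough for stable interval
estimates at n = 2,000. Exact oracles back the small components: brute-
force support sums for moments, scalar hand arithmetic for WAIC, 1-D
quadrature refits for exact LOO, and quadrature of the exact posterior
for the flat conjugate check. Generator calibration is tested with a
3×MC-SE tolerance inflated for the clustering design effect (±0.35 on
the mean, ±1.5 on the variance at n ≈ 10^4).

## Known limitations

- Random-walk sampling needs many iterations for high-dimensional
  fixed-effect blocks; the full covariate design (~40 columns) mixes
  slowly and benefits from longer warmup than the desk defaults.
- PSIS-LOO with heavy posterior tails (k-hat > 0.7) is unreliable;
  flagged observations should be refit exactly.
- The bounded outcome is modelled with unbounded count likelihoods,
  mirroring the emulated analysis; near the cap this is a model
  misspecification by construction (the generator quantifies it via the
  logged truncated fraction).
- Zero-part random effects are implemented but off by default, and the
  builtin backend is the only sampler; gradient-based backends are out
  of scope.
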