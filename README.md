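# transientmpm

Decompose the stochastic dynamics of stage-structured populations into
**asymptotic** and **transient** components.

Plant demographers summarize a population by a matrix population model
(MPM): a non-negative projection matrix **A** that maps the vector of stage
abundances forward one year, `x(t+1) = A(t) x(t)`.  In a variable
environment the realized one-step growth rate factorizes exactly as

```
lambda_obs(t) = lambda_max(t) * reactivity(t)
```

where `lambda_obs = ||A x||₁ / ||x||₁` is the observed growth,
`lambda_max` is the dominant eigenvalue of **A**(t) (the growth the
population *would* have at its stable stage structure **w**), and
`reactivity` is the one-step amplification ("boom", > 1) or attenuation
("bust", < 1) caused by the current structure deviating from **w**.  On the
log scale the decomposition is additive,

```
log lambda_obs = log lambda_max + log reactivity,
```

and because the two terms can oppose each other, the *absolute dynamic*

```
log lambda_abs = |log lambda_max| + |log reactivity|
```

distinguishes strong-but-opposing forces from genuinely weak dynamics.

The package provides, for users doing comparative plant demography:

* exact eigen-analysis and ergodicity (irreducibility/primitivity) checks
  for projection matrices (`transientmpm.core`);
* the per-timestep decomposition above (`transientmpm.decomposition`);
* the stochastic simulation protocol — equal numbers in every stage,
  i.i.d. uniform draws from each population's annual matrices, a 500-step
  burn-in, and 1000 replicate measurements per population
  (`transientmpm.simulate`);
* variance partitioning of each population's replicates into six response
  variables: the shares of observed-growth variance explained by asymptotic
  vs. transient fluctuations (squared Pearson correlations), the mean share
  of the absolute dynamic due to transients, and the mean stochastic,
  asymptotic and transient growth rates (`transientmpm.partition`);
* a synthetic generator for COMPADRE-style databases — species with shared
  growth forms and dimensions, survival/progression/fecundity archetypes,
  lognormal/logit-normal year effects, growth rates centred near 1 — plus
  the standard inclusion filters and a long-format CSV exchange format
  (`transientmpm.synthetic`);
* hierarchical comparative models: logit-proportion regressions on growth
  form and matrix dimension with a species random intercept, an
  intercept-only "boom tendency" test on mean log reactivity, and
  reactivity-growth association tests, with interchangeable ML
  (statsmodels MixedLM) and Gibbs-sampling backends
  (`transientmpm.stats`).

## Worked example

```python
import numpy as np
from transientmpm import (GeneratorConfig, SimulationConfig,
                          generate_database, simulate_database,
                          fit_contribution_model, boom_test)
from transientmpm.partition import summarize_database

db = generate_database(GeneratorConfig(n_species=30, seed=11))
metrics = simulate_database(db.populations,
                            SimulationConfig(n_replicates=200, burn_in=500, seed=7))
summ = summarize_database(db.populations, metrics)
print(summ[["r2_asym", "r2_trans", "prop_abs_trans"]].mean().round(3))

fit = fit_contribution_model(summ, "prop_abs_trans")
print(fit.params.round(3))
```

prints (for these seeds)

```
r2_asym           0.277
r2_trans          0.635
prop_abs_trans    0.500
dtype: float64
                            mean  lower95  upper95  important
parameter
form:herbaceous_perennial -0.656   -1.054   -0.258       True
form:palm                 -1.146   -1.581   -0.711       True
form:shrub                -0.775   -1.321   -0.228       True
form:succulent            -0.709   -1.219   -0.199       True
form:tree                 -1.240   -1.743   -0.736       True
matrix_dimension           0.154    0.082    0.227       True
```

Read: across these 55 synthetic populations, fluctuating asymptotic growth
explains ~28% of the variance in observed growth and reactivity ~64%
(shares overlap, so they need not sum to 1); transients carry ~50% of the
absolute dynamic; and each extra life stage raises the logit of the
transient share by ~0.15 (95% interval excludes zero, so the effect is
"important" in the credible-interval sense).

A command-line pipeline wraps the same steps:

```sh
transientmpm run-all --out results/run1 --seed 1 --replicates 200
```

writes the database, per-replicate metrics, population summaries, all model
fits, diagnostics, exclusion log and a reproducibility manifest.

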