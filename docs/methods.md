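# Methods

## Model

A matrix population model projects stage abundances by a square
non-negative matrix: `x(t+1) = A(t) x(t)`.  For an irreducible, primitive
matrix, Perron–Frobenius theory gives a real, positive, simple dominant
eigenvalue `lambda_max` (the asymptotic growth rate) with a strictly
positive right eigenvector `w` (the stable stage structure, normalized here
to one-norm 1).  The one-step observed growth rate decomposes exactly as

    lambda_obs(t) = ||A(t) x(t)||₁ / ||x(t)||₁
                  = lambda_max(t) · reactivity(t),

with `reactivity(t) = ||(A(t)/lambda_max(t)) · (x(t)/||x(t)||₁)||₁`.
Reactivity equals 1 exactly when `x ∝ w`; values above 1 are transient
amplification ("boom"), below 1 attenuation ("bust").  Natural logs make
the decomposition additive.  Because the two log components may carry
opposite signs, the package also computes the absolute dynamic
`log lambda_abs = |log lambda_max| + |log reactivity|`, which separates
strong-but-opposing forces (where it exceeds `|log lambda_obs|`) from weak
ones (where the two coincide).  In `decompose_step` the transient term is
obtained by subtraction, `log reactivity = log lambda_obs − log
lambda_max`, so the additive identity holds to rounding; the direct
reactivity formula is retained as an independent route and agrees to
< 1e-10, which the test suite asserts on random matrix/vector pairs.

All logs are natural.  Imprimitive-but-irreducible matrices (e.g. 2-stage
Leslie patterns with period 2) are accepted: the pipeline needs only
`lambda_max` and a unique dominant eigenvector, both of which exist there.
A dominant eigenvalue is treated as real when `|imag| ≤ 1e-8·(1+|real|)`
(eigen-solver dust); matrices with a non-simple dominant eigenvalue (e.g.
the identity) raise an ergodicity error from `stable_structure`.
Irreducibility is checked as strong connectivity of the nonzero-pattern
digraph; primitivity by Boolean matrix powers up to the Wielandt exponent
s² − 2s + 2.

## Simulation protocol

Each population holds k ≥ 3 annual matrices.  A replicate starts from equal
abundances in every stage, draws a matrix i.i.d. uniformly (with
replacement, no environmental autocorrelation) each step for a burn-in of
500 steps, then draws one more matrix and records the decomposition of that
single step.  Defaults are 1000 replicates per population.  The stage
vector is renormalized to one-norm 1 every step; every recorded metric
depends on `x` only through `x/||x||₁`, so renormalization changes nothing
(asserted against raw iteration over short horizons) while preventing
overflow across 500 multiplications.  A fresh matrix is drawn for the
measured step itself, consistent with drawing a matrix every interval.
Replicates whose projected abundance hits exactly zero are excluded and
counted; with the strictly positive vital rates the generator produces,
none occur.

Randomness: each population's stream is an independent `numpy` generator
keyed by `SeedSequence([seed, crc32(population_id)])`, so results are
identical no matter in what order (or in how many processes) populations
are simulated.

## Partitioning

Per population, over its replicates: the share of variance in
`log lambda_obs` attributable to asymptotic fluctuation is the squared
Pearson correlation with `log lambda_max`, and to transients the squared
correlation with `log reactivity`; the two shares overlap and need not sum
to 1.  The transient share of the absolute dynamic is the mean of
`|log reactivity| / log lambda_abs`; replicates with `log lambda_abs = 0`
(no dynamics at all) are excluded from that mean as uninformative 0/0
cases, with a count kept.  Correlations use the sample (n−1)
normalization — irrelevant to r² but fixed so the extended-precision oracle
in the tests is exact.  Populations where a component has zero variance
(single-matrix populations) raise an explicit undefined-partition error
rather than returning a degenerate number.

## Synthetic database generator

The generator emulates the statistical shape of a large comparative plant
MPM database: ~100 species, 1–3 populations each (expected ≈ 1.7), matrix
dimension drawn as 2 + Poisson(3.3) truncated to [2, 15] (mean ≈ 5.3),
five growth forms with a herbaceous-dominated mix
(0.55/0.15/0.10/0.08/0.12 over herbaceous perennial/shrub/succulent/palm/
tree), five annual matrices per population, and per-population target
log growth rates N(0, 0.1) — growth rates distributed near 1, as observed
for plants.

Matrix anatomy: column j splits that stage's survival between stasis
(diagonal), progression (subdiagonal) and 5% retrogression (columns ≥ 3);
fecundities fill the top row of the last ⌈s/2⌉ stages with weights rising
1.5× per stage.  Growth-form archetypes set survival ranges and stasis
shares (trees/palms high-stasis, low fecundity variance; herbaceous low
stasis, high fecundity variance).  The mean matrix's fecundities are scaled
by a Brent root-solve so its log dominant eigenvalue hits the population
target to 1e-6; an infeasible target raises a generator error.

Year effects: fecundities are multiplied by mean-preserving lognormal noise
with CV = temporal_cv (scaled by the archetype's fecundity-noise factor);
column survival totals are perturbed on the logit scale (respecting the
column-sum bound ≤ 1) with the sd matched so the implied CV ≈ temporal_cv,
and the stasis/progression/retrogression split is jittered and
renormalized.  Because logit-scale noise biases realized growth downward,
each population's annual set is re-centred by one common fecundity scalar
so the mean of log lambda_max across its annual matrices equals the target;
this keeps the database's overall log-growth distribution centred at zero
without touching the noise structure.  The default temporal CV is 0.3, a
mid-range value for year-to-year vital-rate variation in plants.

Hierarchy for the comparative models: species share a growth form and
dimension and carry a lognormal random intercept on the temporal CV
(sd 0.3 on the log scale), populations a smaller one (sd 0.15), and
`dimension_effect` adds a log-linear coupling of dimension (centred at 5.3)
to the temporal CV.  The generator's bookkeeping frame records each
population's realized CV so recovery experiments can check the injected
structure.  Because that injection acts on the CV scale, the induced
logit-scale dimension slope on the transient proportion has no closed form;
recovery tests therefore compare fitted slopes against the pseudo-true
slope computed from one large reference synthesis under identical settings.

What the generator does *not* emulate: observation error, density
dependence, demographic stochasticity, temporal autocorrelation of
environments, taxonomy/phylogeny, or the long tail of very large matrices.
Passing tests on synthetic data therefore certify the pipeline's
correctness and calibration under the stated model, not conclusions about
real databases.

## Comparative models

Responses (i)–(iii) are proportions and are logit-transformed with clamping
at ε = 1e-6 (smaller than any resolution attainable from 1000 replicates).
Contribution models regress the logit response on growth form and matrix
dimension with a species random intercept; results are reported as one
intercept per growth form (matching per-form prediction plots) though the
fit itself uses treatment coding for numerical stability — the reported
parameters are exact linear transforms of the fitted ones, intervals
included.  A fixed effect is *important* exactly when its 95% interval
excludes zero; no p-value thresholds substitute for this rule.

Two backends honour the same interval contract:

* **mixedlm** (default): statsmodels `MixedLM` (REML), Wald 95% intervals;
  optimizer falls back Powell → Nelder–Mead on numerical failure.  The
  reported `pmcmc` analogue is the two-sided Wald probability.
* **gibbs**: a conjugate Gibbs sampler for the Gaussian linear mixed model,
  run with the long-chain protocol (500,000 iterations, 10% burn-in,
  thinning 250 → ~1800 retained draws), zero-mean normal priors with
  variance 1e10 on fixed effects and inverse-gamma(ν/2, νV/2) priors with
  V = 1, ν = 0.001 on both variance components.  Parameter expansion of the
  random-effect prior is not implemented; with the sample sizes used here
  the plain inverse-gamma prior is effectively overwhelmed by the
  likelihood, and the two backends agree to well within interval widths
  (asserted in the tests).  `pmcmc` is twice the smaller tail fraction of
  the focal chain (floored at 2/n_draws); diagnostics include per-parameter
  effective sample sizes and the lag-1 autocorrelation of the focal chain,
  with convergence flagged when the latter is below 0.1.

The boom test is the intercept-only model with a species random effect on
mean log reactivity; the null expectation is an intercept of zero.  The
association test regresses a growth response (mean log stochastic growth,
or log stable growth of the population's mean matrix) on mean log
reactivity with a species random intercept and reports a likelihood-ratio
chi-squared (1 df) against the no-slope null, with both models refitted by
ML.  A response with numerically zero variance short-circuits to an exact
degenerate fit (point intervals, zero variance components) rather than
passing a singular problem to the optimizer.

## Numerical and design choices

* Zero-variance tolerance for partitions and degenerate fits: relative to
  the data scale (~1e-15·scale, and 1e-12 sd for regression responses).
* Exchange format: dense long CSV (population, species, growth form,
  matrix id, 1-based row/col, value, two boolean flags), values written
  with shortest-round-trip precision so write∘read is the identity.
  The native serialization of public MPM databases is out of scope; an
  external converter can produce this CSV.
* Inclusion filters: ≥ 3 annual matrices, not experimentally manipulated,
  not a mean over matrices; an explicit species exclusion list is supported
  but ships empty.
* Pipeline seeds: generator/simulation/MCMC seeds derive from one global
  seed by a Knuth-style multiplicative hash modulo 2³¹, so a single integer
  reproduces every artefact byte-for-byte.

## Problem sizes

Defaults follow the standard protocol (1000 replicates, burn-in 500,
100-species databases).  The test suite and the headline-recomputation
script use reduced sizes chosen as sufficient for their statistical
purposes: recovery experiments use 30 species × 2 populations at 200
replicates (20 replicate syntheses against a 150-species reference), the
boom-test calibration 40 summary-level null draws, and the smoke test 20
populations at 100 replicates.

## Known limitations

* Phylogenetic covariance structures (and phylogenetic variance ratios)
  are not modelled; the species random intercept is the only grouping.
* The Gibbs backend covers a single random intercept; crossed or nested
  random effects fall back to the species level.
* Wald intervals from the ML backend can undercover slightly at small
  species counts (visible as ~90–95% empirical coverage in the calibration
  tests).
* Multi-step transient indices (amplification envelopes, inertia, Kreiss
  bounds) are out of scope; the decomposition is strictly per-timestep.
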