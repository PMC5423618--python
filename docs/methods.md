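# Methods

## Model

The package fits a two-level non-linear growth model to chronosequence
data.  The observation model treats the height `H_i` (cm) of individual
`i`, at `T_i` years since fire, as lognormal around the species' growth
curve; the process model is the Hillslope re-parameterisation of the
logistic:

    H_i ~ Lognormal(log mu_i, sigma)
    mu_i = alpha_j / (1 + exp(-b_j (T_i - c_j)))

`alpha_j` (cm) is the asymptotic height, `b_j` (cm cm⁻¹ yr⁻¹) the maximum
relative growth rate, and `c_j` (yr) the age at the inflection, where the
absolute growth rate peaks at `alpha*b/4`.  Derived rates follow from
calculus: AGR(T) = `alpha*b*s*(1-s)` and RGR(T) = `b*(1-s)` with
`s = 1/(1+exp(-b(T-c)))`; the identity AGR = RGR·mu is used as a unit test.

**Lognormal convention.** We place the lognormal's log-scale location at
`log mu`, making `mu` the *median* height.  This is the reading consistent
with implementing the model in a BUGS-family sampler, where the lognormal
is parameterised by a log-scale location and precision.  Had `mu` been
taken as the lognormal *mean* instead, the curve would be shifted by
`exp(sigma²/2)` and estimates of `sigma` would move slightly; we expose
`sigma` (log-scale sd) with precision conversions so either convention can
be compared.

**Trait sub-models.** Each log growth parameter is a linear function of
z-scored traits plus a species random effect, e.g.
`log alpha_j = beta0 + beta1·z_SLA,j + eps_j`, `eps_j ~ Normal(0, re_sd)`.
An empty trait structure gives the no-trait baseline (grand means +
between-species sds).  Traits are standardized on the raw scale by default
(an optional per-trait log-before-scaling flag exists, off by default,
since seed mass in particular is conventionally log-transformed); whichever
convention is used, predictions are invariant to the stored units provided
the standardization statistics use the same units.  Ages are treated as
exact — a chronosequence assigns each individual its site's time since
fire.

**Priors.** Coefficients: Normal(0, sd 100) — i.e. precision 1e-4, a vague
prior (`MCMCConfig.prior_beta_sd` makes this configurable; a literal sd of
1e-4 would pin all coefficients at zero and is not a usable reading).  All
standard deviations (observation `sigma`, random-effect `re_sd`, ensemble
`site_sd`): half-Cauchy with scale 25.

**Ensemble variant.** With ≥ 2 ecosystems, each growth parameter's
intercept becomes `beta0 + delta_s`, `delta_s ~ Normal(0, site_sd)` with a
half-Cauchy prior on `site_sd`; traits are standardized on the pooled
table.  Everything else is unchanged, and the model nests the
single-system one as `site_sd -> 0`.

## Sampler

An adaptive random-walk Metropolis-within-Gibbs sampler, written for this
model class because its conditional structure makes each block cheap:

* a joint 3-dimensional update of each species' random effects, vectorized
  across species (the likelihood factorizes by species; per-species sums of
  squared log-residuals are the sufficient quantity and are cached);
* one joint multivariate update of all regression coefficients, with
  per-coordinate scales estimated online (Welford) during burn-in;
* *translation moves* that shift mass along the likelihood-invariant ridges
  a centered parameterization creates: `beta0 -> beta0+d, eps -> eps-d`
  (and the analogous slope↔eps, beta0↔delta, delta_s↔within-system-eps
  moves).  These cost no likelihood evaluation and are what make the
  intercepts and hierarchical sds mix well;
* cheap scalar updates for `log sigma` (reusing cached residuals) and the
  prior-only hierarchical sds.

Proposal scales adapt by Robbins–Monro (target acceptance 0.24 for blocks,
0.44 for scalars) during burn-in only, so the post-burn-in chain is a fixed
Markov kernel.  Defaults: 3 chains, 20 000 iterations, half burn-in, thin
10, over-dispersed initial jitter (sd 0.2 on the log scale) around a
deterministic initialization from single-species least-squares fits of log
heights (box-constrained to avoid the degenerate step-function optimum;
heuristic fallback `alpha = 1.1·max H`, `c = median T`,
`b = 4·max H/(alpha·range T)` for species with < 3 points or no
convergence).  Correctness is tested against the closed-form posterior of
a conjugate reduction (all parameters pinned except one intercept) by
Kolmogorov–Smirnov, and by parameter recovery on synthetic data.

**Convergence.** The Brooks–Gelman–Rubin statistic
`R̂ = sqrt(((n-1)/n·W + B/n)/W)` is computed for every monitored quantity
(coefficients, sds, per-species log parameters); the run is flagged
non-converged — loudly, never silently — if any R̂ exceeds 1.1.  `W = 0` is
reported as undefined (infinite if chains disagree).

## Model checking and selection

* **DIC** in the Spiegelhalter form `DIC = D̄ + pD`, `pD = D̄ − D(θ̄)`,
  with the plug-in point the posterior mean of the *log* species
  parameters and of `log sigma` (medians via a flag).
* **Observed-vs-predicted R²**: squared Pearson correlation of observed
  heights with posterior-median expected heights.
* **Gelman–Pardoe multilevel R²** per sub-model,
  `1 − E[V_j(eps_j)]/E[V_j(log param_j)]`, and **pooling factor**
  `1 − V_j(E[eps_j])/E[V_j(eps_j)]` (sample variances across species,
  expectations over draws; the standard published estimator without
  finite-sample corrections).
* **95%-CI overlap screen**: intervals at most touching → p<0.01; overlap
  less than half the *mean* of the two lengths → p<0.05 (the rule is
  ambiguous about which length; the mean is used).

**Backward selection.** From the full 4-traits × 3-parameters structure,
the slope whose removal least reduces R² is dropped (each candidate
refitted) until any further drop costs more than a tolerance (default
0.005 absolute — deliberately less knife-edge than the differences this
statistic typically shows).  Two scorers are provided.  The *conditional*
scorer (`obs_pred_r2`, the classical choice) includes the species random
effects; because those absorb any dropped trait effect, conditional R² is
nearly flat across structures — reduced models can even score *higher* in
sample — so it selects parsimony, not the generating structure.  The
*marginal* scorer (`trait_only_r2`) predicts every species from the trait
line alone (random effects excluded, as for an unseen species); dropping a
truly active slope then costs R² on the order of the trait effect, and in
simulation this scorer recovers the generating structure reliably.  Use
`score="marginal"` for structure discovery; the conditional scorer remains
the default for continuity with the classical procedure.

## Out-of-sample transfer

For each target species and each retained posterior draw: standardize the
target's traits with the *training* statistics (extrapolation allowed,
logged, never clipped), draw a fresh random effect `eps ~ Normal(0,
re_sd_draw)` per growth parameter, form `alpha, b, c` through the
sub-models and evaluate the curve on an age grid; summarize to the median
and central 95% band.  This is Monte-Carlo imputation of missing heights,
run outside the sampler; a `set eps = 0` mode gives the trait-line point
prediction.  Scoring: RMSD = `sqrt(mean((pred − ref)²))` and MD =
`mean(pred − ref)` (positive = over-prediction), computed by default
against posterior-median curves from a no-trait hierarchical fit to the
target system's own data, on 50 evenly spaced ages spanning the target
chronosequence; a flag scores against raw heights instead.  The identity
`RMSD² = MD² + Var(deviances)` is enforced in tests.

## Synthetic data

The generator mirrors the assumed data-generating process exactly: species
traits from an ecosystem-specific multivariate normal on log scales
(positive, right-skewed traits by construction), species parameters through
the log-linear sub-models (traits standardized with the ecosystem's own
generated sample statistics, recorded in the ground truth), heights
lognormal around the curve, ages drawn from a discrete set of site ages
(default 8 log-spaced sites — chronosequences sample young stands densely;
a continuous-uniform mode exists).  Per-ecosystem intercept offsets create
between-system differences.

Defaults are the package's study conditions: 15 species × 40 individuals,
ages 0.5–25 yr, `beta0 = (log 200, 0.15, log 3)`, slopes −0.3 (SLA→alpha),
+0.3 (leaf N→b), +0.3 (seed mass→c), `re_sd = 0.15`, `sigma = 0.2`.  The
three-system preset places grand-mean log growth rates at +1.35 / +0.15 /
−1.13 with system-specific spreads and a low, narrow SLA distribution in
the fast system, so that simulated transfer fails the way contrasting real
systems do.  What the generator does *not* emulate: intraspecific trait
variation, age measurement error, site-level environmental covariates,
non-logistic growth shapes, or survivorship filtering along the
chronosequence — passing tests therefore demonstrate correctness of the
machinery under the model's own assumptions, not robustness to their
violation.

## Problem sizes and numerical choices

Test-bed experiments are sized for a single CPU: slope recovery uses 10
replicates of the default conditions at 3 chains × 3000 iterations;
structure selection uses 12 species × 12 individuals with strong signal
(slopes ±0.6, `sigma = 0.1`, `re_sd = 0.08`) at 2 chains × 600 iterations —
chain lengths chosen so the Monte-Carlo sd of the selection score (~8e-4)
sits well below the 0.005 tolerance; transfer experiments use a
15-species training system and a 12-species target at 2 chains × 1500
iterations.  Degenerate inputs are refused loudly: non-positive heights or
traits, duplicate records, species with fewer than two distinct ages
(unidentifiable sigmoid), zero-variance training traits.  Ties in backward
selection resolve to the first candidate in the deterministic
(parameter, trait) enumeration; species are always processed in sorted
order, making every fit invariant to input row order.

## Known limitations

* The sampler is random-walk based; posteriors with severe funnels (tiny
  `re_sd` with few species) mix slowly and will be flagged by R̂ rather
  than repaired automatically.
* DIC with lognormal likelihoods shares the usual caveats of plug-in
  deviance measures; no WAIC/LOO is provided.
* Conditional R² cannot identify trait structure (see above); this is a
  property of the statistic, not of the implementation.
* Single trait value per species: intraspecific trait variation is out of
  scope.
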