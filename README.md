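# traitgrowth

Hierarchical Bayesian height-growth models for fire chronosequences, with
functional traits as species-level predictors and a quantitative test of
whether a trait–growth model trained in one ecosystem transfers to species
in another.

## Who this is for

Plant ecologists and biostatisticians who have (or want to simulate)
chronosequence data — heights of individual plants at sites of known time
since fire — together with a species trait table (specific leaf area, wood
density, seed mass, leaf nitrogen), and who want to (i) fit multi-species
non-linear growth trajectories jointly, (ii) ask which traits drive which
growth parameters, and (iii) score out-of-sample predictions for species the
model has never seen, from their traits alone.

## The model

Observed heights are lognormal around a three-parameter logistic
("Hillslope") curve:

    H_i ~ Lognormal(log mu_i, sigma)
    mu_i = alpha_j / (1 + exp(-b_j (T_i - c_j)))

where, for species *j*: `alpha` is the asymptotic height (cm), `b` the
maximum relative growth rate (cm cm⁻¹ yr⁻¹) and `c` the age at maximum
absolute growth (yr).  Each growth parameter is driven by standardized
traits through a log-linear sub-model with a species random effect, e.g.

    log alpha_j = beta0 + beta1 * z(SLA_j) + eps_j ,   eps_j ~ Normal(0, re_sd)

Priors are vague Normals (precision 1e-4) on the coefficients and
half-Cauchy(25) on all standard deviations.  Sampling uses an adaptive
Metropolis-within-Gibbs sampler written for this model class (vectorized
per-species blocks, likelihood-invariant translation moves for the
intercept/slope–random-effect ridges), with the Brooks–Gelman–Rubin R̂
diagnostic, DIC, Gelman–Pardoe multilevel R² and pooling factors for model
checking.  An ensemble variant lets each growth parameter's intercept vary
by ecosystem.

Transferability is tested by predicting the trajectories of species in a
*different* ecosystem from their traits alone (traits standardized with the
*training* statistics, species random effects integrated out by Monte
Carlo), and scoring them against curves fitted to the target system's own
data with RMSD (accuracy) and signed mean deviance MD (bias; positive =
over-prediction).

Because suitable field data are rarely shareable, a first-class synthetic
data module generates multi-ecosystem chronosequences with exactly this
statistical structure (ground truth recorded), including presets for three
qualitative regimes: fast–short–early, intermediate, and slow–tall–late
systems.

## Worked example

```python
import numpy as np
import traitgrowth as tg

# a 15-species x 40-individual chronosequence with known trait effects
cfg = tg.SimulationConfig(seed=42)          # SLA->alpha -0.3, N->b +0.3, SM->c +0.3
ds, truth = tg.generate_multi_ecosystem(cfg)

mc = tg.MCMCConfig(chains=3, iterations=8000, burn_in=4000, thin=10, seed=0)
draws = tg.sample_posterior(ds, tg.TraitStructure.final(), mc)
print("converged:", draws.converged)
for p, t in draws.structure.slopes:
    x = draws.flat(f"beta1_{p}_{t}")
    lo, hi = np.percentile(x, [2.5, 97.5])
    print(f"beta1[{t} -> {p}] = {x.mean():+.3f}  (95% CI {lo:+.3f} to {hi:+.3f})")
score = tg.score_model(draws, ds)
print(f"obs-pred R^2 = {score.obs_pred_r2:.4f}, DIC = {score.dic:.1f} (pD = {score.p_d:.1f})")
```

prints (about 8 s on one CPU):

```
converged: True
beta1[sla -> alpha] = -0.307  (95% CI -0.420 to -0.197)
beta1[leaf_n -> b] = +0.294  (95% CI +0.197 to +0.386)
beta1[seed_mass -> c] = +0.349  (95% CI +0.258 to +0.447)
obs-pred R^2 = 0.9173, DIC = 4395.8 (pD = 42.0)
```

All three 95% credible intervals cover the generating slopes (−0.3, +0.3,
+0.3); the observed-vs-predicted R² says the fitted curves explain ~92% of
the variance in individual heights; pD ≈ 42 is the effective number of
parameters after hierarchical shrinkage (45 species parameters plus
hyperparameters, partially pooled).

The same pipeline is scriptable from the shell:

```bash
traitgrowth simulate --config sim.yaml --seed 1 --out-dir data/
traitgrowth fit --config fit.yaml --seed 2 --out-dir fit/
traitgrowth evaluate --config eval.yaml --seed 0 --out-dir eval/
traitgrowth predict --config pred.yaml --seed 3 --out-dir pred/
traitgrowth transfer-report --config transfer.yaml --seed 4 --out-dir report/
```

Each stage exchanges plain CSV/JSON files and is byte-reproducible for a
fixed seed.

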