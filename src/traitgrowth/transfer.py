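"""Out-of-sample prediction to new species and transferability scoring.

A trait model fitted in one ecosystem predicts the growth trajectory of a
species it has never seen from that species' traits alone: for every
posterior draw the new species' traits are z-scored with the *training*
statistics, a fresh species random effect is drawn from the fitted
random-effect distribution, the growth parameters are formed through the
trait sub-models and the Hillslope curve is evaluated on an age grid.  This
is the Monte-Carlo imputation of missing heights, run outside the sampler.

Predictions are scored against *reference* trajectories — by default the
posterior-median curves of a hierarchical model fitted to the target
ecosystem's own height data — with RMSD (accuracy) and the signed mean
deviance MD (bias; positive = over-prediction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import Dataset, StandardizationStats
from .growth import PredictedTrajectory
from .model import PARAM_NAMES, MCMCConfig, PosteriorDraws, TraitStructure, sample_posterior

logger = logging.getLogger(__name__)

__all__ = [
    "TransferReport",
    "predict_new_species",
    "fitted_trajectories",
    "rmsd",
    "mean_deviance",
    "transfer_report",
]


def rmsd(predicted, reference) -> float:
    """Root mean squared deviance (cm) between aligned height vectors."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {r.shape}")
    return float(np.sqrt(np.mean((p - r) ** 2)))


def mean_deviance(predicted, reference) -> float:
    """Signed mean deviance (cm): positive = over-prediction."""
    p = np.asarray(predicted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if p.shape != r.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {r.shape}")
    return float(np.mean(p - r))


def predict_new_species(draws: PosteriorDraws, stats: StandardizationStats | None,
                        new_traits: pd.DataFrame, ages,
                        include_random_effects: bool = True,
                        seed: int = 0) -> dict[str, PredictedTrajectory]:
    """Trait-only trajectory predictions with credible bands for new species.

    For each retained posterior draw a fresh species random effect
    ``eps ~ Normal(0, re_sd_draw)`` is drawn per growth parameter (set
    ``include_random_effects=False`` for the trait-line point prediction
    with eps = 0).  Traits are standardized with the training ``stats``;
    values outside the training range extrapolate (logged, not clipped).
    """
    ages = np.asarray(ages, dtype=float)
    structure = draws.structure
    used = structure.all_traits
    if used:
        if stats is None or not stats.mean:
            raise ValueError("a trait model needs training StandardizationStats")
        missing = [t for t in used if t not in new_traits.columns]
        if missing:
            raise ValueError(f"new_traits lacks required trait(s): {missing}")
        for t in used:
            z = stats.standardize_value(t, new_traits[t].to_numpy())
            if np.any(np.abs(z) > 3):
                logger.info("trait %s extrapolates beyond the training range "
                            "(|z| up to %.2f)", t, float(np.max(np.abs(z))))
    species = [str(s) for s in new_traits["species"]]
    M = len(species)
    nd = draws.n_chains * draws.n_draws
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    lp = np.empty((nd, 3, M))
    for i, p in enumerate(PARAM_NAMES):
        lp[:, i, :] = draws.flat(f"beta0_{p}")[:, None]
        for t in structure.traits_for(p):
            z = stats.standardize_value(t, new_traits[t].to_numpy())
            lp[:, i, :] += np.outer(draws.flat(f"beta1_{p}_{t}"), z)
        if include_random_effects:
            re_sd = draws.flat(f"re_sd_{p}")
            lp[:, i, :] += re_sd[:, None] * rng.standard_normal((nd, M))
    a = np.exp(lp[:, 0, :])
    b = np.exp(lp[:, 1, :])
    c = np.exp(lp[:, 2, :])
    out: dict[str, PredictedTrajectory] = {}
    for m, sp in enumerate(species):
        with np.errstate(over="ignore"):
            traj = a[:, m, None] / (1.0 + np.exp(-b[:, m, None] * (ages[None, :] - c[:, m, None])))
        med, lo, hi = np.percentile(traj, [50.0, 2.5, 97.5], axis=0)
        out[sp] = PredictedTrajectory(ages=ages, expected_height=med, lower=lo,
                                      upper=hi, species=sp, draws=traj)
    return out


def fitted_trajectories(draws: PosteriorDraws, ages) -> dict[str, np.ndarray]:
    """Posterior-median Hillslope curves of the species in a fit (reference
    curves for transfer scoring)."""
    ages = np.asarray(ages, dtype=float)
    la = draws.samples["log_alpha"].reshape(-1, len(draws.species))
    lb = draws.samples["log_b"].reshape(-1, len(draws.species))
    lc = draws.samples["log_c"].reshape(-1, len(draws.species))
    out = {}
    for j, sp in enumerate(draws.species):
        with np.errstate(over="ignore"):
            traj = np.exp(la[:, j, None]) / (
                1.0 + np.exp(-np.exp(lb[:, j, None]) * (ages[None, :] - np.exp(lc[:, j, None]))))
        out[sp] = np.median(traj, axis=0)
    return out


@dataclass
class TransferReport:
    """Per-species and per-ecosystem RMSD/MD for trait and baseline models."""

    per_species: pd.DataFrame  #: species, ecosystem, model, rmsd_cm, md_cm, n_ages
    per_ecosystem: pd.DataFrame  #: ecosystem, model, rmsd_cm, md_cm

    def to_csv(self, path) -> None:
        self.per_species.to_csv(path, index=False)


def _default_age_grid(target: Dataset, n: int = 50) -> np.ndarray:
    a = target.heights["age_yrs"]
    return np.linspace(float(a.min()), float(a.max()), n)


def transfer_report(trait_draws: PosteriorDraws, baseline_draws: PosteriorDraws,
                    stats: StandardizationStats | None, target: Dataset,
                    ages=None, reference_draws: PosteriorDraws | None = None,
                    reference_config: MCMCConfig | None = None,
                    score_against: str = "fitted", seed: int = 0) -> TransferReport:
    """Score trait-based out-of-sample predictions against the target system.

    Reference trajectories are posterior-median curves from a no-trait
    hierarchical fit to the target data (pass ``reference_draws`` to reuse
    one, or ``reference_config`` to control the internal fit); with
    ``score_against='observed'`` predictions are scored against the raw
    heights at their observed ages instead.  The no-trait ``baseline_draws``
    (fitted to the training data) provide the comparison predictions.
    """
    species = sorted(set(target.heights["species"]))
    if not species:
        return TransferReport(per_species=pd.DataFrame(
            columns=["species", "ecosystem", "model", "rmsd_cm", "md_cm", "n_ages"]),
            per_ecosystem=pd.DataFrame(columns=["ecosystem", "model", "rmsd_cm", "md_cm"]))
    ages = _default_age_grid(target) if ages is None else np.asarray(ages, dtype=float)
    traits = target.traits[target.traits["species"].isin(species)]
    eco_of = dict(zip(traits["species"], traits["ecosystem"]))

    preds_trait = predict_new_species(trait_draws, stats, traits, ages, seed=seed)
    preds_base = predict_new_species(baseline_draws, None, traits, ages,
                                     seed=seed + 1)

    if score_against == "fitted":
        if reference_draws is None:
            cfg = reference_config or MCMCConfig(chains=3, iterations=4000, thin=5, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reference_draws = sample_posterior(target, TraitStructure.none(), cfg)
        refs = fitted_trajectories(reference_draws, ages)
    elif score_against == "observed":
        refs = None
    else:
        raise ValueError("score_against must be 'fitted' or 'observed'")

    rows = []
    for sp in species:
        if refs is not None:
            if sp not in refs:
                logger.warning("species %r lacks a target-fit reference; skipped", sp)
                continue
            ref = refs[sp]
            for model, preds in (("trait", preds_trait), ("baseline", preds_base)):
                pred = preds[sp].expected_height
                rows.append({"species": sp, "ecosystem": eco_of[sp], "model": model,
                             "rmsd_cm": rmsd(pred, ref), "md_cm": mean_deviance(pred, ref),
                             "n_ages": len(ages)})
        else:
            obs = target.heights[target.heights["species"] == sp]
            t_obs = obs["age_yrs"].to_numpy()
            h_obs = obs["height_cm"].to_numpy()
            for model, draws in (("trait", trait_draws), ("baseline", baseline_draws)):
                pr = predict_new_species(draws, stats if model == "trait" else None,
                                         traits[traits["species"] == sp], t_obs,
                                         seed=seed)[sp].expected_height
                rows.append({"species": sp, "ecosystem": eco_of[sp], "model": model,
                             "rmsd_cm": rmsd(pr, h_obs), "md_cm": mean_deviance(pr, h_obs),
                             "n_ages": len(t_obs)})
    per_species = pd.DataFrame(rows)
    per_eco = (per_species.groupby(["ecosystem", "model"], as_index=False)
               .agg(rmsd_cm=("rmsd_cm", "mean"), md_cm=("md_cm", "mean")))
    return TransferReport(per_species=per_species, per_ecosystem=per_eco)
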