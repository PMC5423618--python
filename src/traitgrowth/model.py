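"""Hierarchical Bayesian growth model and MCMC sampler.

Model
-----
Observed heights are lognormal around the Hillslope curve::

    H_i ~ Lognormal(log mu_i, sigma)          (sigma = log-scale sd)
    mu_i = alpha_j / (1 + exp(-b_j (T_i - c_j)))

and each species growth parameter is driven by (standardized) functional
traits through a log-linear sub-model with a species random effect::

    log alpha_j = beta0_a + sum_t beta1_{a,t} z_{t,j} + eps_{a,j}
    log b_j     = beta0_b + ...
    log c_j     = beta0_c + ...
    eps_{p,j} ~ Normal(0, re_sd_p)

With an empty trait structure this is the no-trait baseline model (grand
means + between-species sds).  The ensemble variant adds a system-varying
intercept ``delta_{p,s} ~ Normal(0, site_sd_p)`` per growth parameter.

Priors: Normal(0, prior_beta_sd) on every beta (default sd 100, i.e. a vague
prior with precision 1e-4), half-Cauchy(scale 25) on all standard deviations
(re_sd, sigma, site_sd).

Sampler
-------
Adaptive random-walk Metropolis-within-Gibbs on log-scale blocks:

* a joint per-species update of the three random effects (vectorized over
  species — the likelihood factorizes by species);
* a joint multivariate update of all free regression coefficients, with
  per-coordinate scales estimated during burn-in;
* translation moves that shift mass between an intercept/slope and the
  random effects without changing the likelihood (they remove the ridge a
  centered parameterization otherwise induces);
* cheap scalar updates for sigma (residuals are cached) and the
  hierarchical sds (prior-only).

Proposal scales adapt by Robbins-Monro during burn-in only.  Runs are fully
reproducible from ``MCMCConfig.seed``.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .data_io import TRAIT_NAMES, Dataset, StandardizationStats, ValidationError

PARAM_NAMES = ("alpha", "b", "c")
_LOG_2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "PARAM_NAMES",
    "TraitStructure",
    "MCMCConfig",
    "PosteriorDraws",
    "ConvergenceWarning",
    "log_posterior",
    "init_from_single_species",
    "sample_posterior",
    "fit_ensemble",
    "rhat",
    "rhat_from_chains",
]


class ConvergenceWarning(UserWarning):
    """Raised (as a warning) when R-hat exceeds the configured threshold."""


# ---------------------------------------------------------------------------
# Structures and configuration


@dataclass(frozen=True)
class TraitStructure:
    """Which traits drive which growth parameter (empty = no-trait model)."""

    alpha: tuple[str, ...] = ()
    b: tuple[str, ...] = ()
    c: tuple[str, ...] = ()

    def __post_init__(self):
        for p in PARAM_NAMES:
            ts = getattr(self, p)
            if len(set(ts)) != len(ts):
                raise ValueError(f"duplicate trait in sub-model for {p}: {ts}")
            for t in ts:
                if t not in TRAIT_NAMES:
                    raise ValueError(f"unknown trait {t!r} (known: {TRAIT_NAMES})")

    def traits_for(self, param: str) -> tuple[str, ...]:
        return getattr(self, param)

    @property
    def slopes(self) -> tuple[tuple[str, str], ...]:
        return tuple((p, t) for p in PARAM_NAMES for t in self.traits_for(p))

    @property
    def n_slopes(self) -> int:
        return len(self.slopes)

    @property
    def is_empty(self) -> bool:
        return self.n_slopes == 0

    @property
    def all_traits(self) -> tuple[str, ...]:
        seen = dict.fromkeys(itertools.chain(self.alpha, self.b, self.c))
        return tuple(seen)

    def drop(self, param: str, trait: str) -> "TraitStructure":
        kw = {p: tuple(t for t in self.traits_for(p) if not (p == param and t == trait))
              for p in PARAM_NAMES}
        return TraitStructure(**kw)

    @classmethod
    def full(cls, traits=TRAIT_NAMES) -> "TraitStructure":
        return cls(alpha=tuple(traits), b=tuple(traits), c=tuple(traits))

    @classmethod
    def none(cls) -> "TraitStructure":
        return cls()

    @classmethod
    def final(cls) -> "TraitStructure":
        """SLA -> asymptotic height, leaf N -> growth rate, seed mass -> timing."""
        return cls(alpha=("sla",), b=("leaf_n",), c=("seed_mass",))

    def to_dict(self) -> dict:
        return {p: list(self.traits_for(p)) for p in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "TraitStructure":
        return cls(**{p: tuple(d.get(p, ())) for p in PARAM_NAMES})


@dataclass
class MCMCConfig:
    """Sampler settings.  ``fixed`` pins named quantities (natural scale):
    keys ``beta0_<param>``, ``sigma``, ``re_sd_<param>``, ``eps_<param>``
    (the last fixes the whole random-effect row, typically at 0)."""

    chains: int = 3
    iterations: int = 20_000
    burn_in: int | None = None  #: defaults to iterations // 2
    thin: int = 10
    seed: int = 0
    jitter_sd: float = 0.2  #: per-chain over-dispersion of the initial state
    prior_beta_sd: float = 100.0  #: Normal prior sd on coefficients (precision 1e-4)
    sd_prior_scale: float = 25.0  #: half-Cauchy scale for all sds
    rhat_threshold: float = 1.1
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.burn_in is None:
            self.burn_in = self.iterations // 2
        if not (0 <= self.burn_in < self.iterations):
            raise ValueError("need 0 <= burn_in < iterations")
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin

    def to_dict(self) -> dict:
        return {
            "chains": self.chains, "iterations": self.iterations,
            "burn_in": self.burn_in, "thin": self.thin, "seed": self.seed,
            "jitter_sd": self.jitter_sd, "prior_beta_sd": self.prior_beta_sd,
            "sd_prior_scale": self.sd_prior_scale,
            "rhat_threshold": self.rhat_threshold, "fixed": dict(self.fixed),
        }


# ---------------------------------------------------------------------------
# Model data (design arrays)


class _ModelData:
    """Arrays used by the likelihood; species sorted for order invariance."""

    def __init__(self, dataset: Dataset, structure: TraitStructure,
                 ensemble: bool = False, log_traits: tuple[str, ...] = ()):
        dataset.validate()
        self.structure = structure
        self.ensemble = ensemble
        heights = dataset.heights.sort_values(
            ["species", "individual_id"], kind="mergesort").reset_index(drop=True)
        self.species = sorted(set(heights["species"]))
        sp_pos = {s: i for i, s in enumerate(self.species)}
        self.S = len(self.species)
        self.sp_idx = heights["species"].map(sp_pos).to_numpy(dtype=np.intp)
        self.age = heights["age_yrs"].to_numpy(dtype=float)
        self.H = heights["height_cm"].to_numpy(dtype=float)
        self.logH = np.log(self.H)
        self.N = len(self.age)
        self.n_sp = np.bincount(self.sp_idx, minlength=self.S).astype(float)
        # per-species constant part of the loglik (independent of parameters)
        self.const_sp = -0.5 * _LOG_2PI * self.n_sp - np.bincount(
            self.sp_idx, self.logH, minlength=self.S)

        traits = dataset.traits.set_index("species")
        traits = traits.loc[self.species]
        self.ecosystems = sorted(set(dataset.heights["ecosystem"]))
        if ensemble:
            if len(self.ecosystems) < 2:
                raise ValidationError(
                    "ensemble model needs >= 2 ecosystems; use sample_posterior")
            eco_pos = {e: i for i, e in enumerate(self.ecosystems)}
            self.n_sys = len(self.ecosystems)
            self.sys_of_species = traits["ecosystem"].map(eco_pos).to_numpy(dtype=np.intp)
        else:
            self.n_sys = 0
            self.sys_of_species = None

        used = structure.all_traits
        if used:
            self.stats = StandardizationStats.from_traits(
                traits.reset_index(), traits_used=used, log_traits=log_traits,
                ecosystem="+".join(self.ecosystems))
        else:
            self.stats = StandardizationStats(mean={}, sd={}, ecosystem="+".join(self.ecosystems))
        self.Z = {}
        for i, p in enumerate(PARAM_NAMES):
            cols = [self.stats.standardize_value(t, traits[t].to_numpy())
                    for t in structure.traits_for(p)]
            self.Z[p] = np.column_stack(cols) if cols else np.zeros((self.S, 0))

    # ---- likelihood machinery -------------------------------------------

    def species_log_params(self, state: dict) -> np.ndarray:
        """(3, S) array of log alpha_j, log b_j, log c_j from the state."""
        lp = state["beta0"][:, None] + state["eps"]
        for i, p in enumerate(PARAM_NAMES):
            if self.Z[p].shape[1]:
                lp[i] = lp[i] + self.Z[p] @ state["beta1"][p]
        if self.ensemble and state.get("delta") is not None:
            lp = lp + state["delta"][:, self.sys_of_species]
        return lp

    def ssr_by_species(self, lp: np.ndarray):
        """Per-species sum of squared log-residuals and the residual vector."""
        x = np.exp(lp[1])[self.sp_idx] * (self.age - np.exp(lp[2])[self.sp_idx])
        logmu = lp[0][self.sp_idx] - np.logaddexp(0.0, -x)
        r = self.logH - logmu
        ssr_sp = np.bincount(self.sp_idx, r * r, minlength=self.S)
        return ssr_sp, logmu

    def loglik_sp(self, ssr_sp: np.ndarray, log_sigma: float) -> np.ndarray:
        inv2 = 0.5 * math.exp(-2.0 * log_sigma)
        return -inv2 * ssr_sp - self.n_sp * log_sigma + self.const_sp


def _halfcauchy_logpdf(x, scale):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        return -np.inf
    return float(np.sum(np.log(2.0 / (np.pi * scale)) - np.log1p((x / scale) ** 2)))


def _normal_logpdf_sum(x, sd):
    x = np.asarray(x, dtype=float)
    return float(-0.5 * np.sum((x / sd) ** 2) - x.size * (math.log(sd) + 0.5 * _LOG_2PI))


def _log_prior(md: _ModelData, state: dict, prior_beta_sd: float, sd_scale: float) -> float:
    lp = 0.0
    betas = [state["beta0"]] + [state["beta1"][p] for p in PARAM_NAMES]
    for arr in betas:
        lp += _normal_logpdf_sum(arr, prior_beta_sd)
    re_sd = np.exp(state["log_re_sd"])
    for i in range(3):
        lp += _normal_logpdf_sum(state["eps"][i], re_sd[i])
    lp += _halfcauchy_logpdf(re_sd, sd_scale)
    lp += _halfcauchy_logpdf(np.exp(state["log_sigma"]), sd_scale)
    if md.ensemble:
        site_sd = np.exp(state["log_site_sd"])
        for i in range(3):
            lp += _normal_logpdf_sum(state["delta"][i], site_sd[i])
        lp += _halfcauchy_logpdf(site_sd, sd_scale)
    return lp


def log_posterior(dataset: Dataset, structure: TraitStructure, state: dict,
                  prior_beta_sd: float = 100.0, sd_prior_scale: float = 25.0,
                  ensemble: bool = False) -> float:
    """Unnormalized log posterior density (natural-scale parameters).

    ``state`` uses the internal layout: ``beta0`` (3,), ``beta1`` dict of
    arrays per growth parameter, ``eps`` (3, S) in the sorted-species order,
    ``log_re_sd`` (3,), ``log_sigma`` float, and for the ensemble model
    ``delta`` (3, n_systems), ``log_site_sd`` (3,).  The density is with
    respect to the natural parameters (sigma, re_sd), not their logs.
    """
    md = _ModelData(dataset, structure, ensemble=ensemble)
    _validate_state(md, state)
    lp = md.species_log_params(state)
    ssr_sp, _ = md.ssr_by_species(lp)
    ll = float(np.sum(md.loglik_sp(ssr_sp, state["log_sigma"])))
    return ll + _log_prior(md, state, prior_beta_sd, sd_prior_scale)


def _validate_state(md: _ModelData, state: dict) -> None:
    if np.shape(state["beta0"]) != (3,):
        raise ValueError("state['beta0'] must have shape (3,)")
    if np.shape(state["eps"]) != (3, md.S):
        raise ValueError(f"state['eps'] must have shape (3, {md.S})")
    for p in PARAM_NAMES:
        k = md.Z[p].shape[1]
        if np.shape(state["beta1"][p]) != (k,):
            raise ValueError(f"state['beta1'][{p!r}] must have shape ({k},)")


# ---------------------------------------------------------------------------
# Initialization


def _heuristic_params(t: np.ndarray, h: np.ndarray) -> np.ndarray:
    alpha0 = 1.1 * float(np.max(h))
    c0 = float(np.median(t))
    rng_t = float(np.ptp(t)) or 1.0
    b0 = 4.0 * float(np.max(h)) / (alpha0 * rng_t)
    return np.log([alpha0, b0, max(c0, 1e-3)])


def _curve(t, la, lb, lc):
    return la - np.logaddexp(0.0, -np.exp(lb) * (t - np.exp(lc)))


def _fit_single_species(t: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Deterministic per-species least-squares fit of log heights; falls
    back to a heuristic when the sigmoid cannot be fitted.

    The fit is box-constrained to keep it away from the degenerate
    step-function optimum (huge b, c below the youngest site) that an
    unconstrained logistic fit can reach on noisy chronosequence data.
    """
    x0 = _heuristic_params(t, h)
    if len(t) < 3 or len(np.unique(t)) < 2:
        return x0
    t_lo = max(float(np.min(t)), 1e-3)
    t_hi = float(np.max(t))
    lo = [math.log(0.5 * np.max(h)), math.log(1e-3), math.log(0.5 * t_lo)]
    hi = [math.log(20.0 * np.max(h)), math.log(20.0), math.log(2.0 * t_hi)]
    x0 = np.clip(x0, np.array(lo) + 1e-6, np.array(hi) - 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_curve, t, np.log(h), p0=x0, bounds=(lo, hi),
                                maxfev=2000)
        if np.all(np.isfinite(popt)):
            return popt
    except Exception:
        pass
    return x0


def init_from_single_species(dataset: Dataset, structure: TraitStructure = TraitStructure.none(),
                             ensemble: bool = False) -> dict:
    """Deterministic initial state from independent single-species fits.

    Each species' Hillslope curve is least-squares fitted to its log heights
    (heuristic fallback when degenerate); the coefficients are initialized by
    regressing the fitted log parameters on the standardized traits, the
    random effects by the residuals.
    """
    md = _ModelData(dataset, structure, ensemble=ensemble)
    return _init_state(md)


def _init_state(md: _ModelData) -> dict:
    lp0 = np.empty((3, md.S))
    for j in range(md.S):
        m = md.sp_idx == j
        lp0[:, j] = _fit_single_species(md.age[m], md.H[m])
    state: dict = {"beta1": {}}
    eps = np.empty((3, md.S))
    beta0 = np.empty(3)
    for i, p in enumerate(PARAM_NAMES):
        X = np.column_stack([np.ones(md.S), md.Z[p]])
        coef, *_ = np.linalg.lstsq(X, lp0[i], rcond=None)
        beta0[i] = coef[0]
        state["beta1"][p] = coef[1:].copy()
        eps[i] = lp0[i] - X @ coef
    state["beta0"] = beta0
    state["eps"] = eps
    re_sd = np.maximum(np.std(eps, axis=1, ddof=1) if md.S > 1 else np.full(3, 0.2), 0.05)
    state["log_re_sd"] = np.log(re_sd)
    ssr_sp, _ = md.ssr_by_species(md.species_log_params(state))
    sigma0 = max(math.sqrt(float(np.sum(ssr_sp)) / md.N), 0.02)
    state["log_sigma"] = math.log(sigma0)
    if md.ensemble:
        state["delta"] = np.zeros((3, md.n_sys))
        state["log_site_sd"] = np.log(np.full(3, 0.2))
    return state


def _apply_fixed(md: _ModelData, state: dict, fixed: dict) -> dict:
    """Pin named quantities; returns a free-mask dict used by the sampler."""
    free = {
        "eps": np.ones(3, dtype=bool),
        "beta0": np.ones(3, dtype=bool),
        "re_sd": np.ones(3, dtype=bool),
        "sigma": True,
    }
    for key, val in fixed.items():
        if key == "sigma":
            state["log_sigma"] = math.log(val)
            free["sigma"] = False
            continue
        kind, _, pname = key.rpartition("_")
        if pname not in PARAM_NAMES or kind not in ("beta0", "eps", "re_sd"):
            raise ValueError(f"unknown fixed quantity {key!r}")
        i = PARAM_NAMES.index(pname)
        if kind == "beta0":
            state["beta0"][i] = val
            free["beta0"][i] = False
        elif kind == "eps":
            state["eps"][i, :] = val
            free["eps"][i] = False
        else:  # re_sd_<param>
            state["log_re_sd"][i] = math.log(val)
            free["re_sd"][i] = False
    return free


# ---------------------------------------------------------------------------
# The sampler


class _Adapt:
    """Robbins-Monro scale adaptation toward a target acceptance rate."""

    def __init__(self, scale, target):
        self.log_scale = np.atleast_1d(np.log(np.asarray(scale, dtype=float)))
        self.target = target
        self.t = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self, accepted):
        self.t += 1
        gamma = self.t ** -0.6
        self.log_scale += gamma * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_scale, -12.0, 6.0, out=self.log_scale)


def _run_chain(md: _ModelData, state: dict, free: dict, cfg: MCMCConfig,
               rng: np.random.Generator, record: dict) -> None:
    S, sd_scale, beta_sd = md.S, cfg.sd_prior_scale, cfg.prior_beta_sd
    eps_rows = np.flatnonzero(free["eps"])
    # free coefficient coordinates: (param_index, slot) with slot -1 = intercept
    beta_coords = [(i, -1) for i in range(3) if free["beta0"][i]]
    beta_coords += [(i, k) for i, p in enumerate(PARAM_NAMES)
                    for k in range(md.Z[p].shape[1])]
    d_beta = len(beta_coords)

    lp = md.species_log_params(state)
    ssr_sp, _ = md.ssr_by_species(lp)

    a_eps = _Adapt(0.1, 0.24)
    a_beta = _Adapt(0.1, 0.24 if d_beta > 1 else 0.44)
    a_shift = _Adapt(np.full(3, 0.1), 0.44)
    a_slope = {p: _Adapt(np.full(md.Z[p].shape[1], 0.1), 0.44) for p in PARAM_NAMES}
    a_sigma = _Adapt(0.1, 0.44)
    a_resd = _Adapt(np.full(3, 0.3), 0.44)
    a_delta = _Adapt(np.full(3, 0.1), 0.24) if md.ensemble else None
    a_sitesd = _Adapt(np.full(3, 0.3), 0.44) if md.ensemble else None
    # per-coordinate scale estimate for the joint beta block (Welford)
    beta_mean = np.zeros(d_beta)
    beta_m2 = np.zeros(d_beta)
    beta_n = 0

    def beta_vec():
        return np.array([state["beta0"][i] if k < 0 else state["beta1"][PARAM_NAMES[i]][k]
                         for i, k in beta_coords])

    def set_beta(v):
        for (i, k), x in zip(beta_coords, v):
            if k < 0:
                state["beta0"][i] = x
            else:
                state["beta1"][PARAM_NAMES[i]][k] = x

    rec_i = 0
    for it in range(cfg.iterations):
        adapting = it < cfg.burn_in
        sigma2 = math.exp(2.0 * state["log_sigma"])
        inv2s = 0.5 / sigma2

        # --- species random-effects block (joint over the free rows) ------
        if len(eps_rows):
            step = a_eps.scale * rng.standard_normal((len(eps_rows), S))
            eps_new = state["eps"].copy()
            eps_new[eps_rows] += step
            lp_new = lp.copy()
            lp_new[eps_rows] += step
            ssr_new, _ = md.ssr_by_species(lp_new)
            dll = -inv2s * (ssr_new - ssr_sp)
            re_sd = np.exp(state["log_re_sd"])
            dpr = np.zeros(S)
            for r in eps_rows:
                dpr += -0.5 * (eps_new[r] ** 2 - state["eps"][r] ** 2) / re_sd[r] ** 2
            acc = np.log(rng.random(S)) < dll + dpr
            if np.any(acc):
                state["eps"][np.ix_(eps_rows, np.flatnonzero(acc))] = \
                    eps_new[np.ix_(eps_rows, np.flatnonzero(acc))]
                lp[:, acc] = lp_new[:, acc]
                ssr_sp[acc] = ssr_new[acc]
            if adapting:
                a_eps.update(float(np.mean(acc)))

        # --- joint coefficient block --------------------------------------
        if d_beta:
            cur = beta_vec()
            if adapting:
                beta_n += 1
                d = cur - beta_mean
                beta_mean += d / beta_n
                beta_m2 += d * (cur - beta_mean)
            sd_est = np.sqrt(beta_m2 / max(beta_n - 1, 1)) if beta_n > 10 else np.full(d_beta, 0.05)
            sd_est = np.maximum(sd_est, 1e-4)
            prop = cur + a_beta.scale * sd_est * rng.standard_normal(d_beta) / math.sqrt(d_beta)
            old = cur.copy()
            set_beta(prop)
            lp_new = md.species_log_params(state)
            ssr_new, _ = md.ssr_by_species(lp_new)
            dpost = (-inv2s * float(np.sum(ssr_new - ssr_sp))
                     - 0.5 * float(np.sum(prop**2 - old**2)) / beta_sd**2)
            if math.log(rng.random()) < dpost:
                lp, ssr_sp = lp_new, ssr_new
                acc_b = 1.0
            else:
                set_beta(old)
                acc_b = 0.0
            if adapting:
                a_beta.update(acc_b)

        # --- translation moves (likelihood-invariant) ---------------------
        re_sd = np.exp(state["log_re_sd"])
        for i in range(3):
            if not (free["beta0"][i] and free["eps"][i]):
                continue
            d0 = a_shift.scale[i] * rng.standard_normal()
            e = state["eps"][i]
            dpost = (-0.5 * (((state["beta0"][i] + d0) ** 2 - state["beta0"][i] ** 2) / beta_sd**2)
                     - 0.5 * float(np.sum((e - d0) ** 2 - e**2)) / re_sd[i] ** 2)
            acc = math.log(rng.random()) < dpost
            if acc:
                state["beta0"][i] += d0
                state["eps"][i] -= d0
            if adapting:
                a_shift.update(np.where(np.arange(3) == i, float(acc), a_shift.target))
        for i, p in enumerate(PARAM_NAMES):
            kk = md.Z[p].shape[1]
            if not kk or not free["eps"][i]:
                continue
            for k in range(kk):
                d1 = a_slope[p].scale[k] * rng.standard_normal()
                z = md.Z[p][:, k]
                b1 = state["beta1"][p][k]
                e = state["eps"][i]
                e_new = e - d1 * z
                dpost = (-0.5 * (((b1 + d1) ** 2 - b1**2) / beta_sd**2)
                         - 0.5 * float(np.sum(e_new**2 - e**2)) / re_sd[i] ** 2)
                acc = math.log(rng.random()) < dpost
                if acc:
                    state["beta1"][p][k] = b1 + d1
                    state["eps"][i] = e_new
                if adapting:
                    a_slope[p].update(np.where(np.arange(kk) == k, float(acc), 0.44))

        # --- ensemble system offsets --------------------------------------
        if md.ensemble:
            site_sd = np.exp(state["log_site_sd"])
            for i in range(3):
                step = a_delta.scale[i] * rng.standard_normal(md.n_sys)
                lp_new = lp.copy()
                lp_new[i] += step[md.sys_of_species]
                ssr_new, _ = md.ssr_by_species(lp_new)
                d_sp = -inv2s * (ssr_new - ssr_sp)
                dll_sys = np.bincount(md.sys_of_species, d_sp, minlength=md.n_sys)
                dnew = state["delta"][i] + step
                dpr = -0.5 * (dnew**2 - state["delta"][i] ** 2) / site_sd[i] ** 2
                acc = np.log(rng.random(md.n_sys)) < dll_sys + dpr
                if np.any(acc):
                    acc_sp = acc[md.sys_of_species]
                    state["delta"][i][acc] = dnew[acc]
                    lp[i][acc_sp] = lp_new[i][acc_sp]
                    ssr_sp[acc_sp] = ssr_new[acc_sp]
                if adapting:
                    a_delta.update(np.where(np.arange(3) == i, float(np.mean(acc)),
                                            a_delta.target))
                # delta_s <-> within-system random effects translation
                if free["eps"][i]:
                    re_sd_i = math.exp(state["log_re_sd"][i])
                    for s in range(md.n_sys):
                        mask = md.sys_of_species == s
                        ds_ = a_shift.scale[i] * rng.standard_normal()
                        e = state["eps"][i][mask]
                        dnew = state["delta"][i][s] + ds_
                        dpost = (-0.5 * ((dnew**2 - state["delta"][i][s] ** 2)
                                         / site_sd[i] ** 2)
                                 - 0.5 * float(np.sum((e - ds_) ** 2 - e**2)) / re_sd_i**2)
                        if math.log(rng.random()) < dpost:
                            state["delta"][i][s] = dnew
                            state["eps"][i][mask] -= ds_
                # beta0 <-> delta translation
                if free["beta0"][i]:
                    d0 = a_shift.scale[i] * rng.standard_normal()
                    dl = state["delta"][i]
                    dpost = (-0.5 * (((state["beta0"][i] + d0) ** 2 - state["beta0"][i] ** 2)
                                     / beta_sd**2)
                             - 0.5 * float(np.sum((dl - d0) ** 2 - dl**2)) / site_sd[i] ** 2)
                    if math.log(rng.random()) < dpost:
                        state["beta0"][i] += d0
                        state["delta"][i] -= d0
                # site sd (prior-only, log-scale with Jacobian)
                x = state["log_site_sd"][i]
                x_new = x + a_sitesd.scale[i] * rng.standard_normal()
                dpost = (_normal_logpdf_sum(state["delta"][i], math.exp(x_new))
                         - _normal_logpdf_sum(state["delta"][i], math.exp(x))
                         + _halfcauchy_logpdf(math.exp(x_new), sd_scale)
                         - _halfcauchy_logpdf(math.exp(x), sd_scale)
                         + x_new - x)
                acc = math.log(rng.random()) < dpost
                if acc:
                    state["log_site_sd"][i] = x_new
                if adapting:
                    a_sitesd.update(np.where(np.arange(3) == i, float(acc), a_sitesd.target))

        # --- observation sd (residuals cached) ----------------------------
        if free["sigma"]:
            x = state["log_sigma"]
            x_new = x + float(a_sigma.scale[0]) * rng.standard_normal()
            ssr = float(np.sum(ssr_sp))
            dll = (-0.5 * math.exp(-2 * x_new) * ssr - md.N * x_new) - \
                  (-0.5 * math.exp(-2 * x) * ssr - md.N * x)
            dpr = (_halfcauchy_logpdf(math.exp(x_new), sd_scale)
                   - _halfcauchy_logpdf(math.exp(x), sd_scale) + x_new - x)
            acc = math.log(rng.random()) < dll + dpr
            if acc:
                state["log_sigma"] = x_new
            if adapting:
                a_sigma.update(float(acc))

        # --- random-effect sds (prior-only) -------------------------------
        for i in range(3):
            if not free["re_sd"][i]:
                continue
            x = state["log_re_sd"][i]
            x_new = x + a_resd.scale[i] * rng.standard_normal()
            dpost = (_normal_logpdf_sum(state["eps"][i], math.exp(x_new))
                     - _normal_logpdf_sum(state["eps"][i], math.exp(x))
                     + _halfcauchy_logpdf(math.exp(x_new), sd_scale)
                     - _halfcauchy_logpdf(math.exp(x), sd_scale)
                     + x_new - x)
            acc = math.log(rng.random()) < dpost
            if acc:
                state["log_re_sd"][i] = x_new
            if adapting:
                a_resd.update(np.where(np.arange(3) == i, float(acc), a_resd.target))

        # --- record --------------------------------------------------------
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            for i, p in enumerate(PARAM_NAMES):
                record[f"beta0_{p}"][rec_i] = state["beta0"][i]
                record[f"re_sd_{p}"][rec_i] = math.exp(state["log_re_sd"][i])
                record[f"eps_{p}"][rec_i] = state["eps"][i]
                record[f"log_{p}"][rec_i] = lp[i]
                for k, t in enumerate(md.structure.traits_for(p)):
                    record[f"beta1_{p}_{t}"][rec_i] = state["beta1"][p][k]
                if md.ensemble:
                    record[f"delta_{p}"][rec_i] = state["delta"][i]
                    record[f"site_sd_{p}"][rec_i] = math.exp(state["log_site_sd"][i])
            record["sigma"][rec_i] = math.exp(state["log_sigma"])
            rec_i += 1


# ---------------------------------------------------------------------------
# Posterior draws container


@dataclass
class PosteriorDraws:
    """MCMC samples (chains x draws [x species/system]) plus run metadata."""

    samples: dict[str, np.ndarray]
    species: list[str]
    structure: TraitStructure
    stats: StandardizationStats
    config: MCMCConfig
    ecosystems: list[str]
    ensemble: bool = False
    rhat_table: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    @property
    def n_chains(self) -> int:
        return next(iter(self.samples.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.samples.values())).shape[1]

    def names(self) -> list[str]:
        return sorted(self.samples)

    def get(self, name: str) -> np.ndarray:
        """Chains x draws array; 'eps_alpha[<species>]' selects one species."""
        if "[" in name:
            base, _, rest = name.partition("[")
            label = rest.rstrip("]")
            arr = self.samples[base]
            cols = self.species if base.startswith(("eps_", "log_")) else self.ecosystems
            return arr[:, :, cols.index(label)]
        return self.samples[name]

    def flat(self, name: str) -> np.ndarray:
        arr = self.get(name)
        return arr.reshape(-1, *arr.shape[2:])

    def species_log_param_means(self) -> pd.DataFrame:
        """Posterior-mean log growth parameters per species (point summary)."""
        out = {p: self.samples[f"log_{p}"].mean(axis=(0, 1)) for p in PARAM_NAMES}
        return pd.DataFrame(out, index=pd.Index(self.species, name="species")).rename(
            columns={p: f"log_{p}" for p in PARAM_NAMES})

    def scalar_names(self) -> list[str]:
        return sorted(k for k, v in self.samples.items() if v.ndim == 2)

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, quantity, value) table of all draws."""
        rows = []
        for name in self.names():
            arr = self.samples[name]
            if arr.ndim == 2:
                labels = [name]
                flat = arr[:, :, None]
            else:
                cols = self.species if name.startswith(("eps_", "log_")) else self.ecosystems
                labels = [f"{name}[{c}]" for c in cols]
                flat = arr
            for k, lab in enumerate(labels):
                for ch in range(arr.shape[0]):
                    rows.append(pd.DataFrame({
                        "chain": ch, "iteration": np.arange(arr.shape[1]),
                        "quantity": lab, "value": flat[ch, :, k]}))
        return pd.concat(rows, ignore_index=True)

    def save(self, out_dir) -> None:
        """Write tidy draws CSV + JSON manifest (seed, config, R-hat table)."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_tidy_frame().to_csv(out / "draws.csv", index=False)
        manifest = {
            "species": self.species,
            "ecosystems": self.ecosystems,
            "ensemble": self.ensemble,
            "structure": self.structure.to_dict(),
            "stats": self.stats.to_dict(),
            "config": self.config.to_dict(),
            "rhat": {k: (None if not np.isfinite(v) else round(float(v), 6))
                     for k, v in sorted(self.rhat_table.items())},
            "converged": bool(self.converged),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, out_dir) -> "PosteriorDraws":
        from pathlib import Path

        out = Path(out_dir)
        with open(out / "manifest.json") as fh:
            man = json.load(fh)
        tidy = pd.read_csv(out / "draws.csv")
        species = [str(s) for s in man["species"]]
        ecosystems = [str(e) for e in man["ecosystems"]]
        n_chains = int(tidy["chain"].max()) + 1
        n_draws = int(tidy["iteration"].max()) + 1
        samples: dict[str, np.ndarray] = {}
        for lab, grp in tidy.groupby("quantity", sort=False):
            if "[" in lab:
                base, _, rest = lab.partition("[")
                label = rest.rstrip("]")
                cols = species if base.startswith(("eps_", "log_")) else ecosystems
                if base not in samples:
                    samples[base] = np.empty((n_chains, n_draws, len(cols)))
                tgt = samples[base][:, :, cols.index(label)]
            else:
                base = lab
                samples[base] = np.empty((n_chains, n_draws))
                tgt = samples[base]
            g = grp.sort_values(["chain", "iteration"])
            tgt[...] = g["value"].to_numpy().reshape(n_chains, n_draws)
        cfg_d = man["config"]
        cfg = MCMCConfig(**cfg_d)
        obj = cls(samples=samples, species=species,
                  structure=TraitStructure.from_dict(man["structure"]),
                  stats=StandardizationStats.from_dict(man["stats"]) if man["stats"]["sd"]
                  else StandardizationStats(mean={}, sd={},
                                            ecosystem=man["stats"].get("ecosystem", "")),
                  config=cfg, ecosystems=ecosystems, ensemble=man["ensemble"],
                  rhat_table={k: (np.nan if v is None else v)
                              for k, v in man.get("rhat", {}).items()},
                  converged=man.get("converged", True))
        return obj


# ---------------------------------------------------------------------------
# Diagnostics


def rhat_from_chains(x: np.ndarray) -> float:
    """Potential scale reduction factor for a (chains, draws) array.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B = n * variance of the chain means.  W = 0 is degenerate:
    returns inf (flagged) when the chains disagree, NaN when they are all
    constant and identical.
    """
    x = np.asarray(x, dtype=float)
    m, n = x.shape
    if m < 2 or n < 2:
        raise ValueError("need >= 2 chains and >= 2 draws per chain")
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    B = n * float(np.var(np.mean(x, axis=1), ddof=1))
    if W == 0.0:
        if B > 0.0:
            warnings.warn("R-hat undefined (within-chain variance 0, chains differ)",
                          ConvergenceWarning)
            return float("inf")
        warnings.warn("R-hat undefined (all chains constant)", ConvergenceWarning)
        return float("nan")
    return math.sqrt(((n - 1) / n * W + B / n) / W)


def rhat(draws: PosteriorDraws, quantity: str) -> float:
    """Brooks-Gelman-Rubin diagnostic for one monitored quantity."""
    arr = draws.get(quantity)
    if arr.ndim != 2:
        raise ValueError(f"{quantity!r} is vector-valued; index a species, e.g. "
                         f"'{quantity}[{draws.species[0]}]'")
    return rhat_from_chains(arr)


def _monitored(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    out = {}
    for name, arr in draws.samples.items():
        if name.startswith("eps_"):
            continue  # random effects are monitored through log_<param>
        if arr.ndim == 2:
            out[name] = arr
        else:
            cols = draws.species if name.startswith("log_") else draws.ecosystems
            for k, c in enumerate(cols):
                out[f"{name}[{c}]"] = arr[:, :, k]
    return out


# ---------------------------------------------------------------------------
# Fitting front-ends


def _allocate_record(md: _ModelData, n_draws: int) -> dict:
    rec: dict[str, np.ndarray] = {"sigma": np.empty(n_draws)}
    for p in PARAM_NAMES:
        rec[f"beta0_{p}"] = np.empty(n_draws)
        rec[f"re_sd_{p}"] = np.empty(n_draws)
        rec[f"eps_{p}"] = np.empty((n_draws, md.S))
        rec[f"log_{p}"] = np.empty((n_draws, md.S))
        for t in md.structure.traits_for(p):
            rec[f"beta1_{p}_{t}"] = np.empty(n_draws)
        if md.ensemble:
            rec[f"delta_{p}"] = np.empty((n_draws, md.n_sys))
            rec[f"site_sd_{p}"] = np.empty(n_draws)
    return rec


def _jitter_state(state: dict, free: dict, sd: float, rng: np.random.Generator) -> dict:
    st = {
        "beta0": state["beta0"].copy(),
        "beta1": {p: state["beta1"][p].copy() for p in PARAM_NAMES},
        "eps": state["eps"].copy(),
        "log_re_sd": state["log_re_sd"].copy(),
        "log_sigma": state["log_sigma"],
    }
    if "delta" in state:
        st["delta"] = state["delta"].copy()
        st["log_site_sd"] = state["log_site_sd"].copy()
    if sd <= 0:
        return st
    for i in range(3):
        if free["beta0"][i]:
            st["beta0"][i] += sd * rng.standard_normal()
        if free["eps"][i]:
            st["eps"][i] += sd * rng.standard_normal(st["eps"].shape[1])
        if free["re_sd"][i]:
            st["log_re_sd"][i] += sd * rng.standard_normal()
    for p in PARAM_NAMES:
        st["beta1"][p] += sd * rng.standard_normal(st["beta1"][p].shape)
    if free["sigma"]:
        st["log_sigma"] += sd * rng.standard_normal()
    if "delta" in st:
        st["delta"] += sd * rng.standard_normal(st["delta"].shape)
        st["log_site_sd"] += sd * rng.standard_normal(3)
    return st


def _sample(md: _ModelData, cfg: MCMCConfig) -> PosteriorDraws:
    base = _init_state(md)
    free = _apply_fixed(md, base, cfg.fixed)
    n_draws = cfg.n_draws
    chains = []
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.chains)
    for ch in range(cfg.chains):
        rng = np.random.default_rng(children[ch])
        st = _jitter_state(base, free, cfg.jitter_sd, rng)
        # re-pin fixed values (jitter never touches them, but be safe)
        _apply_fixed(md, st, cfg.fixed)
        rec = _allocate_record(md, n_draws)
        _run_chain(md, st, free, cfg, rng, rec)
        chains.append(rec)
    samples = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    draws = PosteriorDraws(
        samples=samples, species=md.species, structure=md.structure,
        stats=md.stats, config=cfg, ecosystems=md.ecosystems, ensemble=md.ensemble)
    table = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for name, arr in _monitored(draws).items():
            if np.ptp(arr) == 0:  # fixed quantity
                continue
            table[name] = rhat_from_chains(arr)
    draws.rhat_table = table
    worst = max(table.values(), default=1.0)
    draws.converged = bool(worst <= cfg.rhat_threshold)
    if not draws.converged:
        bad = {k: round(v, 3) for k, v in table.items() if v > cfg.rhat_threshold}
        warnings.warn(
            f"MCMC may not have converged: R-hat > {cfg.rhat_threshold} for {bad}",
            ConvergenceWarning)
    return draws


def sample_posterior(dataset: Dataset, structure: TraitStructure,
                     config: MCMCConfig) -> PosteriorDraws:
    """Draw posterior samples for the (single-system) hierarchical model.

    Traits named in ``structure`` are standardized internally against this
    dataset's trait table; the statistics are stored on the result for later
    out-of-sample prediction.  Chains start from over-dispersed jitter around
    the single-species initialization and the run is reproducible from
    ``config.seed``.  Non-convergence (any R-hat above the threshold) is
    flagged with a ConvergenceWarning and ``draws.converged = False``, never
    silently.
    """
    md = _ModelData(dataset, structure, ensemble=False)
    return _sample(md, config)


def fit_ensemble(dataset: Dataset, structure: TraitStructure,
                 config: MCMCConfig) -> PosteriorDraws:
    """Joint fit of >= 2 ecosystems with system-varying intercepts.

    Identical to :func:`sample_posterior` except each growth parameter's
    intercept becomes ``beta0 + delta_s`` with ``delta_s ~ Normal(0,
    site_sd)`` and a half-Cauchy prior on ``site_sd``; traits are
    standardized on the pooled trait table.
    """
    md = _ModelData(dataset, structure, ensemble=True)
    return _sample(md, config)
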