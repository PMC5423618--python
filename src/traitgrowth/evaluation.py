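"""Model checking, comparison and selection.

* DIC in the Spiegelhalter form: DIC = Dbar + pD, pD = Dbar - D(thetabar),
  with deviance D = -2 * log-likelihood and thetabar the posterior mean of
  the parameters on the log scale (medians available via ``point="median"``).
* Observed-vs-predicted R^2: squared Pearson correlation between observed
  heights and the posterior-median expected height of each individual.
* Gelman & Pardoe multilevel R^2 and pooling factors for the species-level
  trait sub-models.
* Backward selection over trait -> growth-parameter slopes, scored by
  observed-vs-predicted R^2 with a parsimony tolerance.
* The 95%-CI overlap screen (two intervals overlapping by less than half
  their mean length -> p < 0.05; just touching or disjoint -> p < 0.01).
* Pairwise R^2 among species-level log growth parameters (the growth
  "dimensions" analysis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import Dataset
from .model import (PARAM_NAMES, MCMCConfig, PosteriorDraws, TraitStructure,
                    _ModelData, sample_posterior)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelScore",
    "SelectionTrace",
    "dic",
    "obs_pred_r2",
    "trait_only_r2",
    "gelman_r2_submodel",
    "pooling_factor",
    "backward_selection",
    "ci_overlap_test",
    "parameter_pairwise_r2",
    "score_model",
]


def _loglik_of_draw(md: _ModelData, lp: np.ndarray, sigma: float) -> float:
    ssr_sp, _ = md.ssr_by_species(lp)
    return float(np.sum(md.loglik_sp(ssr_sp, float(np.log(sigma)))))


def dic(draws: PosteriorDraws, dataset: Dataset, point: str = "mean") -> tuple[float, float]:
    """Deviance Information Criterion and effective parameter count pD.

    D(theta) = -2 loglik; DIC = Dbar + pD with pD = Dbar - D(thetabar).
    The plug-in point is the posterior mean (default) or median of the
    per-species log growth parameters and of log sigma.
    """
    md = _ModelData(dataset, draws.structure, ensemble=draws.ensemble)
    lps = np.stack([draws.samples[f"log_{p}"] for p in PARAM_NAMES], axis=2)  # C,D,3,S
    C, D = lps.shape[:2]
    lps = lps.reshape(C * D, 3, md.S)
    sig = draws.flat("sigma")
    devs = np.array([-2.0 * _loglik_of_draw(md, lps[i], sig[i]) for i in range(C * D)])
    summ = np.mean if point == "mean" else np.median
    lp_bar = summ(lps, axis=0)
    sigma_bar = float(np.exp(summ(np.log(sig))))
    d_bar = float(np.mean(devs))
    d_at_bar = -2.0 * _loglik_of_draw(md, lp_bar, sigma_bar)
    p_d = d_bar - d_at_bar
    return d_bar + p_d, p_d


def _posterior_median_mu(draws: PosteriorDraws, md: _ModelData) -> np.ndarray:
    lps = np.stack([draws.samples[f"log_{p}"] for p in PARAM_NAMES], axis=2)
    C, D = lps.shape[:2]
    lps = lps.reshape(C * D, 3, md.S)
    logmu = np.empty((C * D, md.N))
    for i in range(C * D):
        _, lm = md.ssr_by_species(lps[i])
        logmu[i] = lm
    return np.exp(np.median(logmu, axis=0))


def obs_pred_r2(draws: PosteriorDraws, dataset: Dataset) -> float:
    """Squared Pearson correlation of observed vs posterior-median heights."""
    md = _ModelData(dataset, draws.structure, ensemble=draws.ensemble)
    if md.N < 3:
        raise ValueError("need >= 3 individuals for an observed-vs-predicted R^2")
    pred = _posterior_median_mu(draws, md)
    r = np.corrcoef(md.H, pred)[0, 1]
    return float(r * r)


def trait_only_r2(draws: PosteriorDraws, dataset: Dataset) -> float:
    """Observed-vs-predicted R^2 with species random effects left out.

    Heights are predicted from the trait lines alone (log param = beta0 +
    sum beta1 z), i.e. as for a species the model has never seen.  Unlike
    :func:`obs_pred_r2` this penalizes removing a truly active trait slope
    — the random effects cannot absorb it — which makes it the scorer of
    choice for structure discovery (``backward_selection(score="marginal")``).
    """
    md = _ModelData(dataset, draws.structure, ensemble=draws.ensemble)
    if md.N < 3:
        raise ValueError("need >= 3 individuals for an observed-vs-predicted R^2")
    nd = draws.n_chains * draws.n_draws
    lp = np.empty((nd, 3, md.S))
    for i, p in enumerate(PARAM_NAMES):
        lp[:, i, :] = draws.flat(f"beta0_{p}")[:, None]
        for k, t in enumerate(draws.structure.traits_for(p)):
            lp[:, i, :] += np.outer(draws.flat(f"beta1_{p}_{t}"), md.Z[p][:, k])
    logmu = np.empty((nd, md.N))
    for i in range(nd):
        _, lm = md.ssr_by_species(lp[i])
        logmu[i] = lm
    pred = np.exp(np.median(logmu, axis=0))
    r = np.corrcoef(md.H, pred)[0, 1]
    return float(r * r)


def gelman_r2_submodel(draws: PosteriorDraws, parameter: str) -> float:
    """Gelman & Pardoe species-level R^2 for one growth parameter's sub-model.

    R^2 = 1 - E[V_j(eps_j)] / E[V_j(log param_j)], the expectation over
    posterior draws of the ratio of residual to total species-level
    variance (sample variances across species).
    """
    if not draws.structure.traits_for(parameter):
        raise ValueError(f"no trait sub-model for {parameter!r} in this fit")
    eps = draws.samples[f"eps_{parameter}"]  # C,D,S
    lp = draws.samples[f"log_{parameter}"]
    v_eps = np.var(eps, axis=2, ddof=1)
    v_tot = np.var(lp, axis=2, ddof=1)
    return float(1.0 - np.mean(v_eps) / np.mean(v_tot))


def pooling_factor(draws: PosteriorDraws, parameter: str) -> float:
    """Gelman & Pardoe pooling factor lambda for one sub-model's random effects.

    lambda = 1 - V_j(E[eps_j]) / E[V_j(eps_j)]: near 1 means species
    estimates are pooled toward the trait line; near 0 means they are
    dominated by the species' own data.
    """
    if not draws.structure.traits_for(parameter):
        raise ValueError(f"no trait sub-model for {parameter!r} in this fit")
    eps = draws.samples[f"eps_{parameter}"]
    e_mean = eps.mean(axis=(0, 1))  # E[eps_j] per species
    v_of_means = float(np.var(e_mean, ddof=1))
    mean_of_vars = float(np.mean(np.var(eps, axis=2, ddof=1)))
    return 1.0 - v_of_means / mean_of_vars


@dataclass
class ModelScore:
    """Fit/checking summary for one fitted model."""

    dic: float
    p_d: float
    obs_pred_r2: float
    gelman_r2: dict
    pooling: dict
    rhat_max: float
    converged: bool

    def to_dict(self) -> dict:
        return {
            "dic": self.dic, "p_d": self.p_d, "obs_pred_r2": self.obs_pred_r2,
            "gelman_r2": self.gelman_r2, "pooling": self.pooling,
            "rhat_max": self.rhat_max, "converged": self.converged,
        }


def score_model(draws: PosteriorDraws, dataset: Dataset) -> ModelScore:
    """DIC, observed-vs-predicted R^2 and sub-model diagnostics in one pass."""
    d, p_d = dic(draws, dataset)
    r2 = obs_pred_r2(draws, dataset)
    g, lam = {}, {}
    for p in PARAM_NAMES:
        if draws.structure.traits_for(p):
            g[p] = gelman_r2_submodel(draws, p)
            lam[p] = pooling_factor(draws, p)
    finite = [v for v in draws.rhat_table.values() if np.isfinite(v)]
    return ModelScore(dic=d, p_d=p_d, obs_pred_r2=r2, gelman_r2=g, pooling=lam,
                      rhat_max=max(finite, default=float("nan")),
                      converged=draws.converged)


# ---------------------------------------------------------------------------
# Backward selection


@dataclass
class SelectionTrace:
    """Trace of backward selection: (structure, R^2, n_slopes) per step."""

    steps: list[tuple[TraitStructure, float, int]]
    chosen: TraitStructure

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for st, r2, n in self.steps:
            rows.append({"n_slopes": n, "obs_pred_r2": r2,
                         **{p: "+".join(st.traits_for(p)) for p in PARAM_NAMES}})
        return pd.DataFrame(rows)


def backward_selection(dataset: Dataset, full: TraitStructure, config: MCMCConfig,
                       tolerance: float = 0.005, score: str = "conditional") -> SelectionTrace:
    """Drop trait->parameter slopes greedily while R^2 barely changes.

    Starting from the full structure, each candidate single-slope removal is
    refitted and scored by observed-vs-predicted R^2; the least harmful slope
    is dropped as long as the loss relative to the current model is at most
    ``tolerance``.  With ``tolerance = inf`` everything is dropped and the
    no-trait model is returned.

    ``score="conditional"`` uses :func:`obs_pred_r2` (predictions include
    the species random effects — the classical criterion, which barely
    distinguishes structures because the random effects absorb dropped trait
    effects); ``score="marginal"`` uses :func:`trait_only_r2`, which does
    discriminate and should be preferred for structure discovery.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if score not in ("conditional", "marginal"):
        raise ValueError("score must be 'conditional' or 'marginal'")
    scorer = obs_pred_r2 if score == "conditional" else trait_only_r2

    def fit_r2(st: TraitStructure) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            draws = sample_posterior(dataset, st, config)
        return scorer(draws, dataset)

    current = full
    r2_cur = fit_r2(current)
    steps = [(current, r2_cur, current.n_slopes)]
    while current.n_slopes:
        best, best_r2 = None, -np.inf
        for p, t in current.slopes:
            cand = current.drop(p, t)
            r2 = fit_r2(cand)
            if r2 > best_r2:
                best, best_r2 = cand, r2
        if r2_cur - best_r2 > tolerance:
            break
        current, r2_cur = best, best_r2
        steps.append((current, r2_cur, current.n_slopes))
        logger.info("backward selection: dropped to %d slopes (R^2 = %.4f)",
                    current.n_slopes, r2_cur)
    return SelectionTrace(steps=steps, chosen=current)


# ---------------------------------------------------------------------------
# Interval screening and parameter correlations


def ci_overlap_test(interval_a: tuple[float, float],
                    interval_b: tuple[float, float]) -> str:
    """Approximate hypothesis screen from two 95% credible intervals.

    Returns 'p<0.01' when the intervals at most touch, 'p<0.05' when they
    overlap by less than half of their mean length, else 'not significant'.
    """
    (a_lo, a_hi), (b_lo, b_hi) = interval_a, interval_b
    if not (a_lo < a_hi and b_lo < b_hi):
        raise ValueError("each interval needs lo < hi")
    overlap = min(a_hi, b_hi) - max(a_lo, b_lo)
    half = 0.25 * ((a_hi - a_lo) + (b_hi - b_lo))  # half the mean length
    if overlap <= 0:
        return "p<0.01"
    if overlap < half:
        return "p<0.05"
    return "not significant"


def parameter_pairwise_r2(draws_by_group: dict[str, PosteriorDraws]) -> pd.DataFrame:
    """Pairwise R^2 among species-level log alpha, log b, log c estimates.

    One row per group (ecosystem fit or ensemble fit) and parameter pair;
    estimates are posterior-mean log parameters per species.
    """
    rows = []
    pairs = [("alpha", "b"), ("alpha", "c"), ("b", "c")]
    for group, draws in draws_by_group.items():
        means = draws.species_log_param_means()
        if len(means) < 3:
            raise ValueError(f"group {group!r} has < 3 species")
        for pa, pb in pairs:
            r = np.corrcoef(means[f"log_{pa}"], means[f"log_{pb}"])[0, 1]
            rows.append({"group": group, "pair": f"{pa}-{pb}", "r2": float(r * r),
                         "sign": float(np.sign(r))})
    return pd.DataFrame(rows)
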