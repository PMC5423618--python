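"""Hierarchical model assembly, initialization, sampling and diagnostics."""

import math
import warnings

import numpy as np
import pytest

import traitgrowth as tg
from traitgrowth.growth import lognormal_loglik
from traitgrowth.model import (PARAM_NAMES, ConvergenceWarning, _ModelData,
                               init_from_single_species, log_posterior,
                               rhat_from_chains)


class TestTraitStructure:
    def test_slopes_and_drop(self):
        st = tg.TraitStructure.full()
        assert st.n_slopes == 12
        st2 = st.drop("alpha", "sla")
        assert st2.n_slopes == 11 and "sla" not in st2.alpha
        assert tg.TraitStructure.none().is_empty

    def test_unknown_trait_rejected(self):
        with pytest.raises(ValueError, match="unknown trait"):
            tg.TraitStructure(alpha=("height",))

    def test_dict_roundtrip(self):
        st = tg.TraitStructure.final()
        assert tg.TraitStructure.from_dict(st.to_dict()) == st


class TestLogPosterior:
    def test_term_by_term_oracle_two_species(self, toy_two_species):
        """Hand-assembled sum of Eq-style terms on a 2-species toy."""
        ds = toy_two_species
        structure = tg.TraitStructure.final()
        md = _ModelData(ds, structure)
        S = md.S
        state = {
            "beta0": np.array([np.log(120.0), np.log(0.5), np.log(6.0)]),
            "beta1": {"alpha": np.array([-0.2]), "b": np.array([0.3]),
                      "c": np.array([0.1])},
            "eps": np.array([[0.05, -0.05], [0.1, -0.1], [0.0, 0.2]]),
            "log_re_sd": np.log([0.3, 0.25, 0.4]),
            "log_sigma": np.log(0.35),
        }
        # independent assembly: observation loglik + random-effect densities
        # + coefficient and sd priors
        expected = 0.0
        zs = {p: md.Z[p][:, 0] if md.Z[p].shape[1] else np.zeros(S)
              for p in PARAM_NAMES}
        lp = {}
        for i, p in enumerate(PARAM_NAMES):
            b1 = state["beta1"][p][0] if len(state["beta1"][p]) else 0.0
            lp[p] = state["beta0"][i] + b1 * zs[p] + state["eps"][i]
        for _, row in ds.heights.iterrows():
            j = md.species.index(row["species"])
            mu = math.exp(lp["alpha"][j]) / (
                1 + math.exp(-math.exp(lp["b"][j]) * (row["age_yrs"] - math.exp(lp["c"][j]))))
            expected += lognormal_loglik(row["height_cm"], mu, 0.35)
        from scipy.stats import cauchy, norm

        for i, p in enumerate(PARAM_NAMES):
            re_sd = math.exp(state["log_re_sd"][i])
            expected += norm.logpdf(state["eps"][i], 0, re_sd).sum()
            expected += norm.logpdf(state["beta0"][i], 0, 100.0)
            expected += norm.logpdf(state["beta1"][p], 0, 100.0).sum()
            expected += math.log(2.0) + cauchy.logpdf(re_sd, 0, 25.0)
        expected += math.log(2.0) + cauchy.logpdf(0.35, 0, 25.0)
        got = log_posterior(ds, structure, state)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_finite_for_any_interior_state(self, toy_two_species):
        ds = toy_two_species
        structure = tg.TraitStructure.none()
        rng = np.random.default_rng(3)
        for _ in range(20):
            state = {
                "beta0": np.array([5.0, 0.0, 1.5]) + rng.normal(0, 2, 3),
                "beta1": {p: np.zeros(0) for p in PARAM_NAMES},
                "eps": rng.normal(0, 1, (3, 2)),
                "log_re_sd": rng.normal(-1, 1, 3),
                "log_sigma": rng.normal(-1, 1),
            }
            assert np.isfinite(log_posterior(ds, structure, state))

    def test_likelihood_collapses_as_sigma_shrinks(self, toy_two_species):
        ds = toy_two_species
        structure = tg.TraitStructure.none()
        vals = []
        for sig in (0.5, 0.05, 0.005):
            state = {
                "beta0": np.array([5.0, 0.0, 1.5]),
                "beta1": {p: np.zeros(0) for p in PARAM_NAMES},
                "eps": np.zeros((3, 2)),
                "log_re_sd": np.log([0.3, 0.3, 0.3]),
                "log_sigma": np.log(sig),
            }
            vals.append(log_posterior(ds, structure, state))
        assert vals[0] > vals[1] > vals[2]

    def test_dimension_mismatch(self, toy_two_species):
        state = {
            "beta0": np.zeros(3),
            "beta1": {p: np.zeros(0) for p in PARAM_NAMES},
            "eps": np.zeros((3, 5)),
            "log_re_sd": np.zeros(3),
            "log_sigma": 0.0,
        }
        with pytest.raises(ValueError, match="shape"):
            log_posterior(toy_two_species, tg.TraitStructure.none(), state)


class TestInitialization:
    def test_noiseless_recovery(self):
        cfg = tg.SimulationConfig(
            ecosystems=[tg.EcosystemConfig(name="e", n_species=8, n_individuals=24)],
            sigma=0.0, seed=5)
        ds, truth = tg.generate_multi_ecosystem(cfg)
        md = _ModelData(ds, tg.TraitStructure.none())
        state = init_from_single_species(ds)
        lp = md.species_log_params(state)
        tp = truth.species_params.set_index("species").loc[md.species]
        true_lp = np.log(tp[["alpha", "b", "c"]].to_numpy(dtype=float).T)
        assert np.max(np.abs(lp - true_lp) / np.abs(true_lp)) < 1e-4

    def test_two_point_species_uses_fallback(self, toy_two_species):
        h = toy_two_species.heights.iloc[[0, 1, 3, 4]].reset_index(drop=True)
        ds = tg.Dataset(heights=h, traits=toy_two_species.traits)
        state = init_from_single_species(ds)
        assert np.all(np.isfinite(state["beta0"]))

    def test_deterministic(self, toy_two_species):
        s1 = init_from_single_species(toy_two_species)
        s2 = init_from_single_species(toy_two_species)
        assert np.array_equal(s1["eps"], s2["eps"])
        assert np.array_equal(s1["beta0"], s2["beta0"])


class TestRhat:
    def test_identical_chains_hand_value(self):
        x = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        assert rhat_from_chains(x) == pytest.approx(math.sqrt(3 / 4))

    def test_disagreeing_constant_chains_flagged(self):
        x = np.array([[0.0] * 4, [10.0] * 4])
        with pytest.warns(ConvergenceWarning):
            assert rhat_from_chains(x) == np.inf

    def test_all_constant_undefined(self):
        with pytest.warns(ConvergenceWarning):
            assert np.isnan(rhat_from_chains(np.ones((2, 4))))

    def test_iid_chains_approach_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 20000))
        assert rhat_from_chains(x) == pytest.approx(1.0, abs=5e-3)

    def test_named_quantity_access(self, training_fit):
        _, _, draws = training_fit
        assert 0.8 < tg.rhat(draws, "sigma") < 1.3
        with pytest.raises(ValueError, match="vector-valued"):
            tg.rhat(draws, "eps_alpha")


class TestSampler:
    def test_same_seed_identical_draws(self, toy_two_species):
        mc = tg.MCMCConfig(chains=2, iterations=200, burn_in=100, thin=2, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = tg.sample_posterior(toy_two_species, tg.TraitStructure.none(), mc)
            d2 = tg.sample_posterior(toy_two_species, tg.TraitStructure.none(), mc)
        for k in d1.samples:
            assert np.array_equal(d1.samples[k], d2.samples[k])

    def test_exact_reconstruction_identity(self, training_fit):
        # log param_j = beta0 + beta1 z_j + eps_j for every stored draw
        ds, _, draws = training_fit
        md = _ModelData(ds, draws.structure)
        for i, p in enumerate(PARAM_NAMES):
            recon = draws.samples[f"beta0_{p}"][:, :, None] + draws.samples[f"eps_{p}"]
            for k, t in enumerate(draws.structure.traits_for(p)):
                recon = recon + draws.samples[f"beta1_{p}_{t}"][:, :, None] * md.Z[p][:, k]
            assert np.max(np.abs(recon - draws.samples[f"log_{p}"])) < 1e-10

    def test_species_params_strictly_positive(self, training_fit):
        _, _, draws = training_fit
        for p in PARAM_NAMES:
            assert np.all(np.isfinite(draws.samples[f"log_{p}"]))
            assert np.all(np.exp(draws.samples[f"log_{p}"]) > 0)

    def test_slope_recovery_in_credible_interval(self, training_fit):
        # the default study conditions: true SLA->alpha slope is -0.3
        _, truth, draws = training_fit
        x = draws.flat("beta1_alpha_sla")
        lo, hi = np.percentile(x, [2.5, 97.5])
        assert lo <= truth.beta1["alpha"]["sla"] <= hi

    def test_ensemble_requires_two_ecosystems(self, toy_two_species):
        mc = tg.MCMCConfig(chains=2, iterations=100, burn_in=50, seed=0)
        with pytest.raises(Exception, match="ensemble|ecosystem"):
            tg.fit_ensemble(toy_two_species, tg.TraitStructure.none(), mc)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            tg.MCMCConfig(chains=1)
        with pytest.raises(ValueError):
            tg.MCMCConfig(iterations=100, burn_in=100)


@pytest.fixture(scope="module")
def ensemble_fits():
    A = tg.EcosystemConfig(name="ecoA", n_species=8, n_individuals=15)
    B = tg.EcosystemConfig(name="ecoB", n_species=8, n_individuals=15,
                           log_offsets={"alpha": 2.0})
    cfg = tg.SimulationConfig(ecosystems=[A, B], beta1={}, seed=21)
    ds, _ = tg.generate_multi_ecosystem(cfg)
    mc = tg.MCMCConfig(chains=2, iterations=1200, burn_in=600, thin=4, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        same = tg.fit_ensemble(
            tg.generate_multi_ecosystem(
                tg.SimulationConfig(ecosystems=[
                    tg.EcosystemConfig(name="ecoA", n_species=8, n_individuals=15),
                    tg.EcosystemConfig(name="ecoB", n_species=8, n_individuals=15)],
                    beta1={}, seed=22))[0],
            tg.TraitStructure.none(), mc)
        shifted = tg.fit_ensemble(ds, tg.TraitStructure.none(), mc)
    return same, shifted


class TestEnsembleRecovery:
    def test_identical_processes_offsets_near_zero(self, ensemble_fits):
        same, _ = ensemble_fits
        delta = same.flat("delta_alpha")  # (draws, n_sys)
        assert np.all(np.abs(np.mean(delta, axis=0)) < 0.5)

    def test_generated_offset_recovered(self, ensemble_fits):
        # ecoB generated with log alpha shifted +2 relative to ecoA
        _, shifted = ensemble_fits
        delta = shifted.flat("delta_alpha")
        diff = np.mean(delta[:, 1] - delta[:, 0])
        assert diff == pytest.approx(2.0, abs=0.6)
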