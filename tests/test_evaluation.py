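"""Model checking and selection: DIC, R^2 variants, pooling, CI screen."""

import warnings

import numpy as np
import pandas as pd
import pytest

import traitgrowth as tg
from traitgrowth.growth import lognormal_loglik
from traitgrowth.model import MCMCConfig, PosteriorDraws, TraitStructure


def _draws(samples, species, structure=None, ecosystems=("eco",)):
    """Hand-built PosteriorDraws for oracle tests (no MCMC involved)."""
    return PosteriorDraws(
        samples={k: np.asarray(v, dtype=float) for k, v in samples.items()},
        species=list(species), structure=structure or TraitStructure.none(),
        stats=tg.StandardizationStats(mean={}, sd={}),
        config=MCMCConfig(chains=2, iterations=20, burn_in=10, thin=1),
        ecosystems=list(ecosystems))


def _one_species_dataset(ages, heights):
    h = pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(len(ages))],
        "species": "sp1", "ecosystem": "eco",
        "age_yrs": ages, "height_cm": heights})
    t = pd.DataFrame({"species": ["sp1"], "ecosystem": ["eco"], "sla": [10.0],
                      "wood_density": [0.6], "seed_mass": [2.0], "leaf_n": [1.5]})
    return tg.Dataset(heights=h, traits=t)


class TestDic:
    def test_point_mass_draws_have_zero_pd(self):
        ds = _one_species_dataset([2.0, 10.0], [20.0, 80.0])
        la, lb, lc, sig = np.log(100.0), np.log(0.5), np.log(5.0), 0.3
        n = 6
        samples = {
            "log_alpha": np.full((2, n, 1), la), "log_b": np.full((2, n, 1), lb),
            "log_c": np.full((2, n, 1), lc), "sigma": np.full((2, n), sig)}
        d, p_d = tg.dic(_draws(samples, ["sp1"]), ds)
        mu = 100.0 / (1 + np.exp(-0.5 * (np.array([2.0, 10.0]) - 5.0)))
        dev = -2 * sum(lognormal_loglik(h, m, sig)
                       for h, m in zip([20.0, 80.0], mu))
        assert p_d == pytest.approx(0.0, abs=1e-10)
        assert d == pytest.approx(dev, rel=1e-12)

    def test_three_draw_hand_oracle(self):
        """DIC from 3 hand-written draws on a 2-observation toy, by hand."""
        ds = _one_species_dataset([2.0, 10.0], [20.0, 80.0])
        las = np.log([90.0, 100.0, 110.0])
        sig = np.array([0.25, 0.3, 0.35])
        lb, lc = np.log(0.5), np.log(5.0)
        samples = {
            "log_alpha": las.reshape(1, 3, 1), "log_b": np.full((1, 3, 1), lb),
            "log_c": np.full((1, 3, 1), lc), "sigma": sig.reshape(1, 3)}

        def dev(la, s):
            mu = np.exp(la) / (1 + np.exp(-0.5 * (np.array([2.0, 10.0]) - 5.0)))
            return -2 * sum(lognormal_loglik(h, m, s)
                            for h, m in zip([20.0, 80.0], mu))

        d_bar = np.mean([dev(la, s) for la, s in zip(las, sig)])
        d_at_bar = dev(np.mean(las), np.exp(np.mean(np.log(sig))))
        expected_pd = d_bar - d_at_bar
        d, p_d = tg.dic(_draws(samples, ["sp1"]), ds)
        assert p_d == pytest.approx(expected_pd, rel=1e-10)
        assert d == pytest.approx(d_bar + expected_pd, rel=1e-10)


class TestObsPredR2:
    def test_perfect_fit_is_one(self):
        cfg = tg.SimulationConfig(
            ecosystems=[tg.EcosystemConfig(name="e", n_species=5, n_individuals=10)],
            sigma=0.0, seed=4)
        ds, truth = tg.generate_multi_ecosystem(cfg)
        sp = sorted(ds.species)
        tp = truth.species_params.set_index("species").loc[sp]
        n = 4
        samples = {
            "log_alpha": np.tile(np.log(tp["alpha"].to_numpy()), (2, n, 1)),
            "log_b": np.tile(np.log(tp["b"].to_numpy()), (2, n, 1)),
            "log_c": np.tile(np.log(tp["c"].to_numpy()), (2, n, 1)),
            "sigma": np.full((2, n), 0.1)}
        r2 = tg.obs_pred_r2(_draws(samples, sp), ds)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_correlation_oracle(self):
        ds = _one_species_dataset([1.0, 4.0, 9.0, 15.0], [12.0, 40.0, 75.0, 95.0])
        la, lb, lc = np.log(100.0), np.log(0.5), np.log(5.0)
        samples = {
            "log_alpha": np.full((2, 3, 1), la), "log_b": np.full((2, 3, 1), lb),
            "log_c": np.full((2, 3, 1), lc), "sigma": np.full((2, 3), 0.2)}
        mu = 100.0 / (1 + np.exp(-0.5 * (np.array([1.0, 4.0, 9.0, 15.0]) - 5.0)))
        expected = np.corrcoef([12.0, 40.0, 75.0, 95.0], mu)[0, 1] ** 2
        got = tg.obs_pred_r2(_draws(samples, ["sp1"]), ds)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_too_few_individuals(self):
        ds = _one_species_dataset([2.0, 10.0], [20.0, 80.0])
        samples = {"log_alpha": np.full((2, 2, 1), 4.0),
                   "log_b": np.full((2, 2, 1), -0.7),
                   "log_c": np.full((2, 2, 1), 1.6), "sigma": np.full((2, 2), 0.2)}
        with pytest.raises(ValueError, match=">= 3"):
            tg.obs_pred_r2(_draws(samples, ["sp1"]), ds)


class TestSubmodelDiagnostics:
    def _crafted(self, eps, logp):
        S = eps.shape[-1]
        species = [f"s{j}" for j in range(S)]
        samples = {"eps_alpha": eps, "log_alpha": logp}
        return _draws(samples, species, structure=TraitStructure(alpha=("sla",)))

    def test_gelman_r2_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        eps = rng.normal(0, 0.5, (2, 30, 8))
        logp = rng.normal(5, 1.0, (2, 30, 8))
        d = self._crafted(eps, logp)
        expected = 1 - np.mean(np.var(eps, axis=2, ddof=1)) / \
            np.mean(np.var(logp, axis=2, ddof=1))
        assert tg.gelman_r2_submodel(d, "alpha") == pytest.approx(expected, rel=1e-12)

    def test_gelman_r2_limits(self):
        # zero residual spread with a real slope -> all variance explained
        z = np.linspace(-2, 2, 10)
        logp = np.tile(5.0 + 0.8 * z, (2, 20, 1))
        eps = np.zeros((2, 20, 10))
        assert tg.gelman_r2_submodel(self._crafted(eps, logp), "alpha") == 1.0
        # no slope: log params equal the random effects (plus constant)
        rng = np.random.default_rng(1)
        eps = rng.normal(0, 0.5, (2, 50, 10))
        assert tg.gelman_r2_submodel(self._crafted(eps, 5.0 + eps), "alpha") == \
            pytest.approx(0.0, abs=1e-12)

    def test_pooling_factor_two_pass_oracle(self):
        rng = np.random.default_rng(2)
        eps = rng.normal(0, 0.5, (2, 40, 6)) + rng.normal(0, 0.3, 6)
        d = self._crafted(eps, eps + 5.0)
        e_mean = eps.mean(axis=(0, 1))
        expected = 1 - np.var(e_mean, ddof=1) / np.mean(np.var(eps, axis=2, ddof=1))
        assert tg.pooling_factor(d, "alpha") == pytest.approx(expected, rel=1e-12)

    def test_pooling_factor_complete_pooling(self):
        # identical posterior means for every species' eps -> lambda = 1
        rng = np.random.default_rng(3)
        noise = rng.normal(0, 0.5, (2, 200, 1))
        eps = np.repeat(noise, 6, axis=2)  # same trace for all species
        d = self._crafted(eps, eps + 5.0)
        assert tg.pooling_factor(d, "alpha") == pytest.approx(1.0, abs=1e-12)

    def test_requires_trait_submodel(self):
        d = _draws({"eps_alpha": np.zeros((2, 5, 3)),
                    "log_alpha": np.zeros((2, 5, 3))}, ["a", "b", "c"])
        with pytest.raises(ValueError, match="sub-model"):
            tg.gelman_r2_submodel(d, "alpha")


@pytest.fixture(scope="module")
def small_dataset():
    cfg = tg.SimulationConfig(
        ecosystems=[tg.EcosystemConfig(name="e", n_species=6, n_individuals=6)],
        seed=8)
    return tg.generate_multi_ecosystem(cfg)[0]


class TestBackwardSelection:
    def test_infinite_tolerance_returns_no_trait_model(self, small_dataset):
        full = TraitStructure(alpha=("sla", "wood_density"), b=("leaf_n",),
                              c=("seed_mass",))
        mc = MCMCConfig(chains=2, iterations=100, burn_in=50, thin=2, seed=1)
        trace = tg.backward_selection(small_dataset, full, mc, tolerance=np.inf)
        assert trace.chosen.is_empty
        assert trace.steps[0][0] == full and trace.steps[0][2] == 4
        assert trace.steps[-1][0].is_empty

    def test_species_order_invariance(self, small_dataset):
        full = TraitStructure(alpha=("sla",), b=("leaf_n",))
        mc = MCMCConfig(chains=2, iterations=100, burn_in=50, thin=2, seed=1)
        shuffled = tg.Dataset(
            heights=small_dataset.heights.sample(frac=1, random_state=0)
            .reset_index(drop=True),
            traits=small_dataset.traits.sample(frac=1, random_state=1)
            .reset_index(drop=True))
        t1 = tg.backward_selection(small_dataset, full, mc, tolerance=np.inf)
        t2 = tg.backward_selection(shuffled, full, mc, tolerance=np.inf)
        assert [s[1] for s in t1.steps] == pytest.approx([s[1] for s in t2.steps])

    def test_negative_tolerance_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            tg.backward_selection(small_dataset, TraitStructure.full(),
                                  MCMCConfig(chains=2, iterations=100, burn_in=50),
                                  tolerance=-1.0)


class TestCiOverlap:
    @pytest.mark.parametrize("a,b,verdict", [
        ((0.0, 1.0), (2.0, 3.0), "p<0.01"),   # disjoint
        ((0.0, 1.0), (1.0, 2.0), "p<0.01"),   # just touching
        ((0.0, 1.0), (0.8, 1.8), "p<0.05"),   # overlap 0.2 < half (0.5)
        ((0.0, 1.0), (0.1, 1.1), "not significant"),  # overlap 0.9 > half
    ])
    def test_verdicts(self, a, b, verdict):
        assert tg.ci_overlap_test(a, b) == verdict
        assert tg.ci_overlap_test(b, a) == verdict

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            tg.ci_overlap_test((1.0, 0.0), (0.0, 1.0))


class TestPairwiseR2:
    def _point_mass(self, log_params, name="g"):
        S = log_params.shape[1]
        sp = [f"{name}{j}" for j in range(S)]
        samples = {f"log_{p}": np.tile(log_params[i], (2, 3, 1))
                   for i, p in enumerate(("alpha", "b", "c"))}
        return _draws(samples, sp)

    def test_known_generating_correlation(self):
        rng = np.random.default_rng(5)
        n = 200
        cov = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, -0.9], [0.0, -0.9, 1.0]])
        lp = rng.multivariate_normal([5.0, 0.2, 1.0], cov * 0.2, n).T
        tab = tg.parameter_pairwise_r2({"g": self._point_mass(lp)})
        bc = tab.query("pair == 'b-c'").iloc[0]
        assert bc["r2"] == pytest.approx(0.81, abs=0.08)
        assert bc["sign"] == -1
        ab = tab.query("pair == 'alpha-b'").iloc[0]
        assert ab["r2"] < 0.05

    def test_pooling_opposite_levels_creates_correlation(self):
        # two groups with opposite alpha/b levels: within-group independent,
        # pooled estimates strongly correlated (the ensemble extra dimension)
        rng = np.random.default_rng(6)
        n = 40
        a1 = rng.multivariate_normal([6.0, -0.8, 1.0], np.eye(3) * 0.04, n).T
        a2 = rng.multivariate_normal([4.0, 0.8, 1.0], np.eye(3) * 0.04, n).T
        pooled = np.concatenate([a1, a2], axis=1)
        tab = tg.parameter_pairwise_r2({
            "g1": self._point_mass(a1, "a"), "g2": self._point_mass(a2, "b"),
            "ens": self._point_mass(pooled, "c")})
        ab = tab.query("pair == 'alpha-b'").set_index("group")["r2"]
        assert ab["ens"] > max(ab["g1"], ab["g2"])
        assert ab["ens"] > 0.8

    def test_too_few_species(self):
        lp = np.zeros((3, 2))
        with pytest.raises(ValueError, match="< 3 species"):
            tg.parameter_pairwise_r2({"g": self._point_mass(lp)})
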