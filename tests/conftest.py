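import numpy as np
import pandas as pd
import pytest

import traitgrowth as tg


@pytest.fixture()
def toy_two_species():
    """A tiny valid dataset: 2 species, 3 observations each, one ecosystem."""
    heights = pd.DataFrame({
        "individual_id": [f"i{k}" for k in range(6)],
        "species": ["sp1"] * 3 + ["sp2"] * 3,
        "ecosystem": "eco",
        "age_yrs": [1.0, 5.0, 20.0, 2.0, 8.0, 25.0],
        "height_cm": [10.0, 60.0, 110.0, 5.0, 30.0, 80.0],
    })
    traits = pd.DataFrame({
        "species": ["sp1", "sp2"],
        "ecosystem": "eco",
        "sla": [8.0, 14.0],
        "wood_density": [0.7, 0.5],
        "seed_mass": [1.2, 4.0],
        "leaf_n": [1.1, 2.0],
    })
    return tg.Dataset(heights=heights, traits=traits)


@pytest.fixture(scope="session")
def training_fit():
    """One moderate fit of the default training system, shared across tests."""
    import warnings

    cfg = tg.SimulationConfig(seed=3)
    ds, truth = tg.generate_multi_ecosystem(cfg)
    mc = tg.MCMCConfig(chains=3, iterations=2000, burn_in=1000, thin=5, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = tg.sample_posterior(ds, tg.TraitStructure.final(), mc)
    return ds, truth, draws


def random_growth_params(rng, n):
    """n random valid GrowthParams spanning realistic magnitudes."""
    alpha = np.exp(rng.uniform(np.log(20), np.log(1000), n))
    b = np.exp(rng.uniform(np.log(0.05), np.log(7.0), n))
    c = np.exp(rng.uniform(np.log(0.5), np.log(20.0), n))
    return [tg.GrowthParams(alpha=a, b=bb, c=cc) for a, bb, cc in zip(alpha, b, c)]
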