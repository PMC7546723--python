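import numpy as np
import pytest

from geacoia.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One study-shaped dataset at desk scale: 5 basins x 4 sites x 8
    individuals, 300 neutral + 20 climate-driven loci."""
    cfg = SimConfig(
        n_basins=5, sites_per_basin=4, inds_per_site=8,
        n_neutral_loci=300, n_selected_loci=20, climate_effect_beta=2.0,
        fst_basin=0.08, fst_site=0.04, missing_rate=0.03, seed=42,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
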