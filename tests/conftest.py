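import warnings

import numpy as np
import pytest

import redlist_gapfill as rg

# Network-learner fits on tiny pools routinely stop at max_iter; that is
# expected behaviour in the test fixtures, not a defect under test.
warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def small_world() -> rg.World:
    return rg.build_world(
        rg.WorldConfig(grid_rows=30, grid_cols=30, cell_km=10.0, pa_fraction=0.15, seed=7)
    )


@pytest.fixture(scope="session")
def small_pool(small_world) -> rg.SpeciesPool:
    return rg.sample_species(
        small_world,
        rg.SpeciesGenConfig(n_species=160, n_families=12, missingness_rates=0.08, seed=11),
    )


@pytest.fixture(scope="session")
def signal_pool(small_world) -> rg.SpeciesPool:
    """Pool with a strong range-size threat signal and no missing traits."""
    return rg.sample_species(
        small_world,
        rg.SpeciesGenConfig(
            n_species=400,
            n_families=15,
            missingness_rates=0.0,
            threat_model=rg.ThreatModel(intercept=-1.0, beta_range=-2.5, beta_size=1.0, beta_growth=-1.0),
            seed=13,
        ),
    )


def model_table(pool: rg.SpeciesPool):
    """Classifier input: predictors + taxonomy + status + range size."""
    table = pool.species.copy()
    table["range_km2"] = table["hull_area_km2"]
    return table


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
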