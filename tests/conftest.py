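import numpy as np
import pytest
from dataclasses import replace

from oceanfarm.config import ScenarioConfig
from oceanfarm.fixtures import default_fishery, default_species
from oceanfarm.life_history import PatchEnvironment, SpeciesParams


@pytest.fixture(scope="session")
def species() -> SpeciesParams:
    return default_species()


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """A 20-patch system for fast equilibrium tests."""
    sp = default_species()
    return ScenarioConfig(
        species=replace(sp, sigma_m=sp.range_fraction * 20 / 4.0),
        fishery=default_fishery(),
        n_patches=20,
        total_biomass_target=200.0,
    )


@pytest.fixture
def uniform_env() -> PatchEnvironment:
    return PatchEnvironment.uniform(10, 5.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
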