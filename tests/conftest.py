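import numpy as np
import pytest

from colimit import (
    CommunityState,
    ModelConfig,
    SpeciesPool,
    SpeciesTraits,
    SupplyVector,
    generate_random_pool,
)


@pytest.fixture
def pool_1x1() -> SpeciesPool:
    """Single species using (c1, n1), equal yields."""
    return SpeciesPool(1, 1, (SpeciesTraits(0, 1, 1, 20.0, 40.0, 0.5, 0.5),))


@pytest.fixture
def pool_2x2() -> SpeciesPool:
    return generate_random_pool(2, 2, rng_seed=1)


@pytest.fixture
def tilman_pool() -> SpeciesPool:
    """Two species on one carbon/nitrogen pair with crossed growth-yield
    ranking: species 0 is the better carbon competitor but has the smaller
    carbon yield (relative to its nitrogen yield). The classic bistable
    configuration for two essential resources."""
    return SpeciesPool(
        1,
        1,
        (
            SpeciesTraits(0, 1, 1, 50.0, 20.0, 0.2, 0.8),
            SpeciesTraits(1, 1, 1, 30.0, 40.0, 0.9, 0.3),
        ),
    )


@pytest.fixture
def balanced_supply() -> SupplyVector:
    return SupplyVector([100.0], [100.0], 1.0)


@pytest.fixture
def config() -> ModelConfig:
    return ModelConfig(rng_seed=0)


def equal_stoichiometry_pool(K: int, M: int, seed: int) -> SpeciesPool:
    """Random pool in which every species has the same Y(n)/Y(c)."""
    from colimit import generate_equal_stoichiometry_pool

    return generate_equal_stoichiometry_pool(K, M, seed)
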