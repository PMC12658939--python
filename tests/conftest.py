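import warnings

import pytest

from paguard.covariates import CONTINUOUS_COVARIATES, assemble_pixel_table
from paguard.rangechange import classify_change, extinction_rate, richness
from paguard.synth import WorldConfig, generate_world

# The canonical standard synthetic world: the package default configuration
# at its default seed.
STANDARD_SEED = 0


def world_pixel_table(world):
    """Assemble the matching pixel table for a generated world."""
    past_rich = richness(world.past)
    lost = [classify_change(p, r).lost for p, r in zip(world.past, world.recent)]
    lost_rich = richness(lost)
    ext = extinction_rate(past_rich, lost_rich)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = assemble_pixel_table(
            ext,
            world.pmap,
            {k: world.covariates[k] for k in CONTINUOUS_COVARIATES},
            world.covariates["bioanthromes"],
        )
    return table


@pytest.fixture(scope="session")
def standard_world():
    return generate_world(WorldConfig(seed=STANDARD_SEED))


@pytest.fixture(scope="session")
def standard_table(standard_world):
    return world_pixel_table(standard_world)


@pytest.fixture(scope="session")
def small_world():
    """A reduced world for fast structural tests."""
    cfg = WorldConfig(
        n_rows=80,
        n_cols=80,
        n_species=15,
        n_pas=25,
        seed=11,
    )
    return generate_world(cfg)
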