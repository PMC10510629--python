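import pytest

from retroroute.scoring import BuildingBlockSet
from retroroute.toyworld import WorldSpec, generate_world, mock_suite


@pytest.fixture(scope="session")
def world():
    """A small, fully deterministic toy universe shared across tests."""
    return generate_world(
        WorldSpec(seed=11, n_building_blocks=14, max_depth=2, max_reactions_per_depth=80)
    )


@pytest.fixture(scope="session")
def suite(world):
    return mock_suite(world)


@pytest.fixture(scope="session")
def bb(world):
    return BuildingBlockSet.from_smiles(world.building_blocks)
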