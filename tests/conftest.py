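import pytest

from aropipe import simulate as sim
from aropipe.orthology import PruningParams, tree_from_newick


@pytest.fixture
def small_config():
    return sim.SimulationConfig(
        n_taxa=6,
        n_families=5,
        duplication_rate=0.5,
        loss_rate=0.3,
        site_count=200,
        seed=11,
    )


@pytest.fixture
def species_tree6(small_config):
    return sim.simulate_species_tree(small_config)


@pytest.fixture
def loose_params():
    """Pruning cutoffs at study defaults but a low minimum-taxa bound."""
    return PruningParams(min_taxa=3)


@pytest.fixture
def quartet_tree():
    return tree_from_newick(
        "((A@1:0.05,B@1:0.02):0.05,(C@1:0.1,D@1:0.1):0.05);"
    )
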