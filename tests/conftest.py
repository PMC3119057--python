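import numpy as np
import pytest

from phylofdp import Phylogeny, SimulationConfig, generate_forest, yule_tree


@pytest.fixture(scope="session")
def yule64():
    """One fixed 64-tip ultrametric Yule tree, root depth 1."""
    return yule_tree(64, np.random.default_rng(2024))


@pytest.fixture(scope="session")
def balanced4():
    """Balanced ultrametric 4-tip tree used by the algebra oracles."""
    return Phylogeny.from_newick("((A:1,B:1):2,(C:2,D:2):1);")


@pytest.fixture(scope="session")
def small_neutral_forest():
    """A small plot with no filtering and no signal (the neutral limit)."""
    cfg = SimulationConfig(
        plot_x_m=200,
        plot_y_m=160,
        n_species=40,
        n_stems=6000,
        signal_strength=0.0,
        filtering_strength=0.0,
        seed=11,
    )
    return generate_forest(cfg)


@pytest.fixture(scope="session")
def small_filtered_forest():
    """A small plot with strong filtering on a strongly heritable preference."""
    cfg = SimulationConfig(
        plot_x_m=200,
        plot_y_m=160,
        n_species=40,
        n_stems=6000,
        signal_strength=1.0,
        filtering_strength=2.0,
        seed=12,
    )
    return generate_forest(cfg)
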