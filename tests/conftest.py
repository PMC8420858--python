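import numpy as np
import pytest

from lrhunt.forest_core import ForestParams, grow_forest
from lrhunt.synth_data import SynthConfig, generate_dataset, make_worked_example_tree


@pytest.fixture(scope="session")
def example_tree():
    return make_worked_example_tree()


# variable indices in the fixture tree
H, V, W, U = 0, 1, 2, 3


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SynthConfig(n_a=40, n_b=40, p_a=6, p_b=6, n_planted=2, n_context=2, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_forest():
    # variables 0 and 1 are active on complementary halves of the cases,
    # mimicking the block structure of an imputed interaction space: one
    # splits a subtree open, the other keeps splitting inside it
    rng = np.random.default_rng(42)
    data = rng.normal(size=(60, 8))
    data[:30, 0] = 3.0 * rng.normal(size=30)
    data[30:, 0] = 0.05 * rng.normal(size=30)
    data[:30, 1] = 0.05 * rng.normal(size=30)
    data[30:, 1] = 3.0 * rng.normal(size=30)
    return grow_forest(data, ForestParams(n_trees=30, seed=5))


def random_small_tree(seed, n=24, p=5, max_depth=5):
    """A random tree with <= 63 nodes for oracle comparisons."""
    rng = np.random.default_rng(seed)
    data = rng.normal(size=(n, p))
    forest = grow_forest(
        data, ForestParams(n_trees=1, nodesize=1, max_depth=max_depth, seed=int(seed))
    )
    return forest.trees[0]
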