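import numpy as np
import pytest

import carapace as cp


@pytest.fixture(scope="session")
def balanced_tree():
    """((A:1,B:1):1,C:2); — the worked three-tip example."""
    return cp.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def study_tree():
    """The 200-tip Yule study tree (height 1), shared across heavy tests."""
    return cp.simulate_tree(cp.SimulationConfig(seed=2024))


@pytest.fixture(scope="session")
def study_vcv(study_tree):
    return study_tree.vcv()


def random_tree(rng: np.random.Generator, n_tips: int, height: float = 1.0):
    """Small random Yule tree with an rng-derived seed."""
    seed = int(rng.integers(0, 2**31 - 1))
    return cp.simulate_tree(
        cp.SimulationConfig(n_tips=n_tips, tree_height=height, seed=seed)
    )
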