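import dendropy
import numpy as np
import pytest

import phylormax as pm


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2); — shared branch of length 1 between A and B."""
    return dendropy.Tree.get(
        data="((A:1,B:1):1,C:2);", schema="newick", preserve_underscores=True
    )


@pytest.fixture(scope="session")
def small_tree():
    return pm.simulate_tree(40, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_tree):
    """40-species trait table simulated from the additive-model truth."""
    cfg = pm.SimulationConfig(
        n_species=40,
        seed=7,
        model="logrmax~logM+1/kBT+depth",
        true_beta=(0.0, -0.3, -0.7, -0.4),
        true_lambda=0.7,
        sigma2=0.3,
    )
    return pm.simulate_pgls_dataset(small_tree, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
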