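import numpy as np
import pytest

from gallimeta import synthetic as syn


@pytest.fixture(scope="session")
def small_taxonomy():
    """1 domain .. 2 genera x 3 species = 6 leaf taxa."""
    return syn.gen_taxonomy([1, 1, 1, 1, 1, 2, 3], seed=11)


@pytest.fixture(scope="session")
def community():
    """Default 90-sample community with 3 planted enterotypes (seed 0)."""
    counts, env, truth = syn.gen_community(n_samples=90, seed=0)
    return counts, env, truth


@pytest.fixture(scope="session")
def rel_abundance(community):
    counts, _, _ = community
    return counts / counts.sum(axis=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
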