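import numpy as np
import pytest

from bindspace import synthetic as syn
from bindspace.structures import ActiveSite


@pytest.fixture(scope="session")
def mdma_like():
    return syn.make_toy_ligand("mdma_like")


@pytest.fixture(scope="session")
def pocket():
    return syn.make_toy_pocket()


@pytest.fixture(scope="session")
def full_site(pocket):
    """Active site covering every pocket residue."""
    return ActiveSite(frozenset(pocket.residue_ids()), radius=6.0)


@pytest.fixture(scope="session")
def mc_system():
    """(pose, receptor, site, monitored pairs) with planted salt bridge + pi."""
    return syn.make_mc_system(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
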