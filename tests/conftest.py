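import numpy as np
import pytest
from hypothesis import settings

from pocketkit import BindingSite
from pocketkit import fixtures as fx

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def toy_msa():
    return fx.make_toy_msa(n_rows=8, length=30, conservation=0.7, seed=11)


@pytest.fixture
def toy_protein():
    return fx.make_toy_protein("ADERFYLVSG")


@pytest.fixture
def toy_site(toy_protein):
    keys = toy_protein.residue_keys()
    return BindingSite(frozenset(keys), cutoff=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
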