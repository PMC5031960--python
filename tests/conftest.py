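import numpy as np
import pytest

from evorec.trees import species_tree


@pytest.fixture(scope="session")
def six_taxon_tree():
    return species_tree()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160922)
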