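import numpy as np
import pytest

from crisprindel.simulate import make_locus, make_panel


@pytest.fixture(scope="session")
def locus_and_cut():
    return make_locus(length=3000, seed=11)


@pytest.fixture(scope="session")
def panel(locus_and_cut):
    locus, cut = locus_and_cut
    return make_panel(locus, cut)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
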