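import numpy as np
import pytest

from triplescan import fixtures as fx


@pytest.fixture()
def gc_pair():
    return fx.compose_triple(fx.wc_gc_pair())


@pytest.fixture()
def au_pair():
    return fx.compose_triple(fx.wc_au_pair())


@pytest.fixture()
def uau_model():
    return fx.compose_triple(fx.uau_triple())


@pytest.fixture()
def gcg_model():
    return fx.compose_triple(fx.gcg_triple())


@pytest.fixture()
def acc_model():
    return fx.compose_triple(fx.acc_protonated_triple())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
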