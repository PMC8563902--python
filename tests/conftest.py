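import numpy as np
import pytest

from trnam1a.simulate import default_truth, make_transcriptome, make_trna_reference


@pytest.fixture(scope="session")
def refs20():
    return make_trna_reference(20, seed=1)


@pytest.fixture(scope="session")
def refs4():
    return make_trna_reference(4, seed=7)


@pytest.fixture(scope="session")
def truth20(refs20):
    return default_truth(refs20, seed=1)


@pytest.fixture(scope="session")
def transcriptome100():
    return make_transcriptome(100, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
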