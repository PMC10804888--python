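import numpy as np
import pytest

from migraph import build_adjacency, build_layout


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def graph(layout):
    return build_adjacency(layout)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
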