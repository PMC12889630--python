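import numpy as np
import pytest

from hypercascade.cascade import EditState, build_site_graph, default_unit_design
from hypercascade.simulate import EditModel


@pytest.fixture(scope="session")
def graph20():
    return build_site_graph(20, terminal_pam_present=True)


@pytest.fixture(scope="session")
def graph4():
    return build_site_graph(4, terminal_pam_present=True)


@pytest.fixture(scope="session")
def design():
    return default_unit_design()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def strict_model():
    return EditModel(variant="strict_hypercascade", layer_rates=(0.01,) * 4)


def random_state(graph, rng, p=0.4):
    """A random (not necessarily reachable) edit state."""
    st = EditState.unedited(graph)
    st.status[:] = (rng.random(graph.n_sites) < p).astype(np.int16)
    return st
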