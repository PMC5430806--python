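import networkx as nx
import numpy as np
import pytest
from hypothesis import settings

from motenet import SimConfig, simulate_study

settings.register_profile("ci", max_examples=25, derandomize=True,
                          deadline=None)
settings.load_profile("ci")

#: Small but fully featured study used by several test modules.
SMALL_CONFIG = SimConfig(n_camps=2, camp_size_range=(16, 20), study_days=5,
                         seed=42)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SMALL_CONFIG)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def graph_from_edges(edges: dict) -> nx.Graph:
    G = nx.Graph()
    for (u, v), w in edges.items():
        G.add_edge(u, v, weight=w)
    return G
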