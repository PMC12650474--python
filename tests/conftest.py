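import numpy as np
import pytest

from nemacontrol.network import DirectedNetwork
from nemacontrol.synthetic import cycle_network, path_network, star_network


@pytest.fixture
def path4():
    return path_network(4)


@pytest.fixture
def star4():
    return star_network(4, "out")


@pytest.fixture
def cycle4():
    return cycle_network(4)


def make_random_digraph(rng: np.random.Generator, n: int, p: float) -> DirectedNetwork:
    """Erdős–Rényi-style random digraph on nodes \"1\"..\"n\" (self-loops allowed)."""
    nodes = [str(i) for i in range(1, n + 1)]
    edges = {(u, v) for u in nodes for v in nodes if rng.random() < p}
    return DirectedNetwork({x: "interneuron" for x in nodes}, edges)
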