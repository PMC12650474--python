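import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching as scipy_matching

from nemacontrol.network import DegenerateNetworkError, DirectedNetwork
from nemacontrol.structural import driver_analysis, maximum_matching
from nemacontrol.synthetic import cycle_network, path_network, star_network

from conftest import make_random_digraph


def scipy_matching_size(net: DirectedNetwork) -> int:
    """Independent maximum-matching cardinality via scipy's csgraph solver."""
    nodes = net.sorted_nodes()
    idx = {n: i for i, n in enumerate(nodes)}
    rows = [idx[u] for u, _ in net.edges]
    cols = [idx[v] for _, v in net.edges]
    bi = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(nodes), len(nodes))
    )
    return int((scipy_matching(bi, perm_type="column") != -1).sum())


def test_path_matching_cardinality(path4):
    assert maximum_matching(path4).cardinality == 3


def test_edgeless_network_has_empty_matching():
    net = DirectedNetwork({str(i): "other" for i in range(1, 5)}, set())
    assert maximum_matching(net).cardinality == 0
    report = driver_analysis(net)
    assert report.num_drivers == 4 and report.driver_density == 1.0


def test_empty_network_is_degenerate():
    with pytest.raises(DegenerateNetworkError):
        maximum_matching(DirectedNetwork({}, set()))


def test_matching_pairs_are_network_edges_and_disjoint():
    rng = np.random.default_rng(3)
    for _ in range(20):
        net = make_random_digraph(rng, 8, 0.3)
        m = maximum_matching(net)
        assert m.pairs <= net.edges
        assert len(m.matched_out) == m.cardinality
        assert len(m.matched_in) == m.cardinality


@pytest.mark.parametrize("n_graphs", [200])
def test_matching_cardinality_agrees_with_scipy_on_random_digraphs(n_graphs):
    rng = np.random.default_rng(11)
    for _ in range(n_graphs):
        net = make_random_digraph(rng, int(rng.integers(2, 7)), rng.uniform(0.1, 0.7))
        assert maximum_matching(net).cardinality == scipy_matching_size(net)


def test_path_driver_analysis(path4):
    report = driver_analysis(path4)
    assert report.num_drivers == 1
    assert report.driver_density == 0.25
    assert report.driver_nodes == ("1",)


@pytest.mark.parametrize("orientation", ["out", "in"])
def test_star_driver_analysis_either_orientation(orientation):
    report = driver_analysis(star_network(4, orientation))
    assert report.num_drivers == 3
    assert report.driver_density == 0.75


def test_cycle_hits_perfect_matching_floor(cycle4):
    report = driver_analysis(cycle4)
    assert report.matching_size == 4
    assert report.num_drivers == 1
    assert report.floor_applied
    assert report.floor_driver == "1"
    assert report.driver_nodes == ()
    # the single shared-signal channel touches the cycle
    (channel,) = report.input_channels()
    assert "1" in channel


def test_self_loop_is_matchable():
    # an autapse matches a node's out-copy to its own in-copy
    net = DirectedNetwork({"A": "other"}, {("A", "A")})
    report = driver_analysis(net)
    assert report.matching_size == 1
    assert report.floor_applied and report.num_drivers == 1
    # with a second node, out-copy A still covers only one in-copy
    net2 = DirectedNetwork({"A": "other", "B": "other"}, {("A", "A"), ("A", "B")})
    assert maximum_matching(net2).cardinality == 1


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=2, max_value=7))
def test_matching_cardinality_invariant_under_relabeling(seed, n):
    rng = np.random.default_rng(seed)
    net = make_random_digraph(rng, n, 0.35)
    perm = rng.permutation(n)
    mapping = {str(i + 1): f"z{perm[i]:02d}" for i in range(n)}
    relabeled = DirectedNetwork(
        {mapping[x]: net.category(x) for x in net.nodes},
        {(mapping[u], mapping[v]) for u, v in net.edges},
    )
    assert (
        maximum_matching(net).cardinality == maximum_matching(relabeled).cardinality
    )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_adding_an_edge_never_increases_drivers(seed):
    rng = np.random.default_rng(seed)
    net = make_random_digraph(rng, 6, 0.25)
    nodes = net.sorted_nodes()
    missing = [
        (u, v) for u in nodes for v in nodes if (u, v) not in net.edges
    ]
    if not missing:
        return
    extra = missing[int(rng.integers(len(missing)))]
    grown = DirectedNetwork(net.categories, set(net.edges) | {extra})
    assert driver_analysis(grown).num_drivers <= driver_analysis(net).num_drivers


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_removing_an_edge_costs_at_most_one_matched_pair(seed):
    rng = np.random.default_rng(seed)
    net = make_random_digraph(rng, 6, 0.35)
    if not net.edges:
        return
    edge = sorted(net.edges)[int(rng.integers(net.n_edges))]
    shrunk = DirectedNetwork(net.categories, set(net.edges) - {edge})
    before = maximum_matching(net).cardinality
    after = maximum_matching(shrunk).cardinality
    assert before - 1 <= after <= before


@settings(max_examples=80, deadline=None, derandomize=True)
@given(
    st.integers(min_value=0, max_value=10_000),
    st.integers(min_value=2, max_value=8),
    st.floats(min_value=0.0, max_value=0.8),
)
def test_driver_count_and_density_bounds(seed, n, p):
    net = make_random_digraph(np.random.default_rng(seed), n, p)
    report = driver_analysis(net)
    assert 1 <= report.num_drivers <= n
    assert 0 < report.driver_density <= 1
    assert report.num_drivers == max(n - report.matching_size, 1)
    assert len(report.driver_nodes) == n - report.matching_size


def test_driver_sets_are_reproducible():
    rng = np.random.default_rng(21)
    for _ in range(10):
        net = make_random_digraph(rng, 7, 0.3)
        assert driver_analysis(net) == driver_analysis(net)
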