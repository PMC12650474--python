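import numpy as np
import pytest

from nemacontrol.ablation import ablate_node, influence_scores
from nemacontrol.io import neural_view
from nemacontrol.synthetic import cycle_network, hub_names, path_network, random_connectome, star_network

from conftest import make_random_digraph


def test_ablating_interior_path_node(path4):
    net = ablate_node(path4, "2")
    assert net.nodes == {"1", "3", "4"}
    assert net.edges == {("3", "4")}


def test_ablating_star_hub_leaves_edgeless_network():
    net = ablate_node(star_network(4, "out"), "1")
    assert net.n_nodes == 3 and net.n_edges == 0


def test_unknown_node_rejected(path4):
    with pytest.raises(KeyError):
        ablate_node(path4, "99")


def test_edge_count_drops_by_total_degree():
    rng = np.random.default_rng(31)
    for _ in range(20):
        net = make_random_digraph(rng, 8, 0.3)
        node = net.sorted_nodes()[int(rng.integers(net.n_nodes))]
        degree = sum(1 for u, v in net.edges if u == node or v == node)
        assert ablate_node(net, node).n_edges == net.n_edges - degree


def test_path_interior_removal_influence_is_hand_computable(path4):
    # removing node 2 leaves {1, 3->4}: drivers {1, 3}, nd = 2/3
    profile = influence_scores(path4)
    assert profile.baseline_nd == 0.25
    assert profile.influence_of("2") == pytest.approx(2 / 3 - 1 / 4)


def test_automorphic_nodes_share_influence():
    star = star_network(5, "out")
    profile = influence_scores(star)
    leaf_scores = {profile.influence_of(x) for x in ("2", "3", "4", "5")}
    assert len(leaf_scores) == 1
    ring = cycle_network(5)
    ring_scores = {r.influence for r in influence_scores(ring).records}
    assert len(ring_scores) == 1


def test_influence_bounds():
    rng = np.random.default_rng(37)
    for _ in range(15):
        net = make_random_digraph(rng, 7, 0.3)
        profile = influence_scores(net)
        n = net.n_nodes
        lo = 1 / (n - 1) - profile.baseline_nd
        hi = 1 - profile.baseline_nd
        assert len(profile.records) == n
        for r in profile.records:
            assert lo - 1e-12 <= r.influence <= hi + 1e-12


def test_ranking_is_a_permutation_and_profile_deterministic():
    net = random_connectome(n_neurons=30, n_muscles=5, mean_degree=6, n_hubs=3, seed=6)
    p1, p2 = influence_scores(net), influence_scores(net)
    assert p1 == p2
    assert sorted(p1.ranking) == net.sorted_nodes()
    df = p1.to_dataframe()
    assert list(df["rank"]) == list(range(1, net.n_nodes + 1))


def test_hub_interneurons_outscore_other_neurons_on_average():
    # hubs sustain many matched edges; their removal should degrade nd most
    hubs = set(hub_names(5))
    for seed in (0, 3):
        net = random_connectome(
            n_neurons=80, n_muscles=14, mean_degree=8, n_hubs=5, seed=seed
        )
        profile = influence_scores(neural_view(net))
        hub_mean = np.mean([r.influence for r in profile.records if r.name in hubs])
        rest_mean = np.mean([r.influence for r in profile.records if r.name not in hubs])
        assert hub_mean >= rest_mean


def test_category_summary_covers_all_categories():
    net = random_connectome(n_neurons=40, n_muscles=8, mean_degree=6, n_hubs=3, seed=8)
    summary = influence_scores(net).category_summary()
    assert set(summary.index) <= {"sensory", "interneuron", "motor", "muscle"}
    assert summary["count"].sum() == net.n_nodes
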