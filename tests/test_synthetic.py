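import time

import pytest

from nemacontrol.structural import driver_analysis
from nemacontrol.synthetic import (
    GrowthConfig,
    cycle_network,
    developmental_series,
    hub_names,
    path_network,
    random_connectome,
    star_network,
)


def test_canonical_topologies():
    assert path_network(4).edges == {("1", "2"), ("2", "3"), ("3", "4")}
    assert star_network(4, "out").edges == {("1", "2"), ("1", "3"), ("1", "4")}
    assert star_network(3, "in").edges == {("2", "1"), ("3", "1")}
    assert cycle_network(3).edges == {("1", "2"), ("2", "3"), ("3", "1")}
    with pytest.raises(ValueError):
        path_network(1)
    with pytest.raises(ValueError):
        star_network(4, "sideways")


def test_star_driver_density_matches_worked_example():
    assert driver_analysis(star_network(4, "out")).driver_density == 0.75


def test_random_connectome_layout():
    net = random_connectome(n_neurons=170, n_muscles=30, mean_degree=8, n_hubs=6, seed=7)
    assert net.n_nodes == 200
    assert len(net.muscles) == 30
    assert len(net.neurons) == 170
    # muscles are pure sinks
    assert all(u not in net.muscles for u, _ in net.edges)
    # every muscle is fed, and predominantly by motor neurons
    pred = net.predecessors()
    feeders = [p for m in net.muscles for p in pred[m]]
    assert all(pred[m] for m in net.muscles)
    motor_share = sum(net.category(p) == "motor" for p in feeders) / len(feeders)
    assert motor_share > 0.5
    assert set(hub_names(6)) <= net.nodes


def test_random_connectome_deterministic_per_seed():
    a = random_connectome(seed=12)
    b = random_connectome(seed=12)
    c = random_connectome(seed=13)
    assert a.edges == b.edges and a.categories == b.categories
    assert c.edges != a.edges


def test_hubs_have_boosted_out_degree():
    net = random_connectome(n_neurons=100, n_muscles=10, mean_degree=8, n_hubs=4, seed=3)
    succ = net.successors()
    hubs = hub_names(4)
    hub_mean = sum(len(succ[h]) for h in hubs) / len(hubs)
    others = [n for n in net.neurons if n not in set(hubs)]
    other_mean = sum(len(succ[n]) for n in others) / len(others)
    assert hub_mean > 2 * other_mean


def test_growth_config_validation():
    with pytest.raises(ValueError):
        GrowthConfig(stages=0)
    with pytest.raises(ValueError):
        GrowthConfig(final_neurons=100, initial_neurons=150)
    with pytest.raises(ValueError):
        GrowthConfig(final_edges=100, initial_edges=700)


def test_series_hits_interpolated_counts_exactly():
    cfg = GrowthConfig(seed=1)
    series = developmental_series(cfg)
    neuron_sched = cfg.neuron_schedule()
    edge_sched = cfg.edge_schedule()
    assert neuron_sched[0] == 161 and neuron_sched[-1] == 180
    assert edge_sched[0] == 675 and edge_sched[-1] == 1933
    for stage, n_target, e_target in zip(series, neuron_sched, edge_sched):
        assert len(stage.network.neurons) == n_target
        assert stage.n_edges == e_target
        assert len(stage.network.muscles) == cfg.muscle_count


def test_series_growth_is_monotone_and_hubs_born_first():
    series = developmental_series(GrowthConfig(seed=5))
    for a, b in zip(series, list(series)[1:]):
        assert a.network.nodes <= b.network.nodes
        assert a.network.edges <= b.network.edges
    assert set(hub_names(6)) <= series[0].network.nodes


def test_series_deterministic_per_seed():
    s1 = developmental_series(GrowthConfig(seed=9))
    s2 = developmental_series(GrowthConfig(seed=9))
    for a, b in zip(s1, s2):
        assert a.network.edges == b.network.edges
        assert a.network.categories == b.network.categories


def test_edge_jitter_allows_non_monotone_counts():
    cfg = GrowthConfig(edge_jitter=0.15, seed=2)
    series = developmental_series(cfg)
    counts = [s.n_edges for s in series]
    assert counts[0] == 675 and counts[-1] == 1933
    # nodes still grow monotonically even when edge counts wobble
    for a, b in zip(series, list(series)[1:]):
        assert a.network.nodes <= b.network.nodes


def test_driver_trajectory_over_series_is_fast():
    series = developmental_series(GrowthConfig(seed=4))
    start = time.perf_counter()
    densities = [driver_analysis(s.network).driver_density for s in series]
    elapsed = time.perf_counter() - start
    assert len(densities) == 8
    assert all(0 < d <= 1 for d in densities)
    assert elapsed < 1.0
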