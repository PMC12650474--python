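"""Synthetic connectome generation.

Everything the analysis pipeline consumes can be generated here: the
canonical toy topologies used in worked examples (path, star, cycle), random
connectome-like networks with categorised cells, and monotone developmental
growth series emulating the expansion of a maturing nervous system (nodes
and edges added stage over stage).

The random generator mimics the structural features the controllability
analysis is sensitive to, not the biology: right-skewed out-degrees (a
truncated geometric law), a few high-out-degree hub interneurons standing in
for command interneurons, and muscles as pure sinks receiving edges
preferentially from motor neurons.  All draws are reproducible from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import DirectedNetwork, Stage, StageSeries

__all__ = [
    "path_network",
    "star_network",
    "cycle_network",
    "random_connectome",
    "hub_names",
    "GrowthConfig",
    "developmental_series",
]


def _toy(n: int, edges, label: str) -> DirectedNetwork:
    if n < 2:
        raise ValueError(f"{label} network needs n >= 2, got {n}")
    return DirectedNetwork(
        {str(i): "interneuron" for i in range(1, n + 1)}, edges, stage_label=label
    )


def path_network(n: int) -> DirectedNetwork:
    """Directed path 1 → 2 → … → n."""
    return _toy(n, [(str(i), str(i + 1)) for i in range(1, n)], "path")


def star_network(n: int, orientation: str = "out") -> DirectedNetwork:
    """Star with hub "1" and n−1 leaves; edges point out of or into the hub."""
    if orientation not in ("out", "in"):
        raise ValueError("orientation must be 'out' or 'in'")
    if orientation == "out":
        edges = [("1", str(i)) for i in range(2, n + 1)]
    else:
        edges = [(str(i), "1") for i in range(2, n + 1)]
    return _toy(n, edges, "star")


def cycle_network(n: int) -> DirectedNetwork:
    """Directed cycle 1 → 2 → … → n → 1."""
    edges = [(str(i), str(i + 1)) for i in range(1, n)] + [(str(n), "1")]
    return _toy(n, edges, "cycle")


def hub_names(n_hubs: int) -> list[str]:
    """Names of the designated hub interneurons, in generation order."""
    return [f"CIN{i:02d}" for i in range(1, n_hubs + 1)]


def _cell_names(n_neurons: int, n_muscles: int, n_hubs: int) -> dict[str, str]:
    """Deterministic name/category layout for a synthetic connectome.

    Roughly C. elegans-like proportions among the non-hub neurons:
    30% sensory, 30% interneurons, 40% motor.  Hubs are interneurons with
    their own CIN prefix so analyses can single them out.
    """
    if n_hubs > n_neurons:
        raise ValueError("more hubs than neurons")
    rest = n_neurons - n_hubs
    n_sen = round(0.3 * rest)
    n_mot = round(0.4 * rest)
    n_int = rest - n_sen - n_mot
    cats: dict[str, str] = {}
    for name in hub_names(n_hubs):
        cats[name] = "interneuron"
    for i in range(1, n_sen + 1):
        cats[f"SEN{i:03d}"] = "sensory"
    for i in range(1, n_int + 1):
        cats[f"INT{i:03d}"] = "interneuron"
    for i in range(1, n_mot + 1):
        cats[f"MOT{i:03d}"] = "motor"
    for i in range(1, n_muscles + 1):
        cats[f"MUS{i:03d}"] = "muscle"
    return cats


def _draw_out_degrees(
    rng: np.random.Generator,
    sources: list[str],
    hubs: set[str],
    mean_out: float,
    hub_boost: float,
    max_degree: int,
) -> dict[str, int]:
    """Truncated-geometric out-degrees (right-skewed), boosted for hubs."""
    if mean_out <= 0 or max_degree < 1:
        raise ValueError("infeasible degree demands")
    p = 1.0 / (1.0 + mean_out)
    degrees = {}
    for name in sources:
        d = int(rng.geometric(p) - 1)
        if name in hubs:
            d = int(round(d * hub_boost)) + int(round(mean_out * hub_boost))
        degrees[name] = min(d, max_degree)
    return degrees


def random_connectome(
    n_neurons: int = 170,
    n_muscles: int = 30,
    mean_degree: float = 8.0,
    n_hubs: int = 6,
    hub_boost: float = 4.0,
    seed: int = 0,
    stage_label: str | None = None,
) -> DirectedNetwork:
    """Random categorised connectome with hub interneurons and sink muscles.

    ``mean_degree`` is the target mean total degree of neurons, so the
    expected edge count is about ``n_neurons * mean_degree / 2``.  Muscles
    have out-degree zero and receive edges preferentially from motor
    neurons; every muscle is guaranteed at least one motor in-edge.
    """
    if n_neurons < 2 or n_muscles < 0:
        raise ValueError("need at least 2 neurons and a nonnegative muscle count")
    rng = np.random.default_rng(seed)
    cats = _cell_names(n_neurons, n_muscles, n_hubs)
    neurons = sorted(n for n, c in cats.items() if c != "muscle")
    muscles = sorted(n for n, c in cats.items() if c == "muscle")
    motors = sorted(n for n, c in cats.items() if c == "motor")
    hubs = set(hub_names(n_hubs))

    degrees = _draw_out_degrees(
        rng, neurons, hubs, mean_degree / 2.0, hub_boost, n_neurons - 1
    )
    edges: set[tuple[str, str]] = set()
    for src in neurons:
        d = degrees[src]
        if d == 0:
            continue
        # motor neurons route about half their output to muscles; other
        # neurons only rarely (muscles remain preferentially motor-fed)
        p_muscle = 0.5 if cats[src] == "motor" else 0.02
        for _ in range(d):
            if muscles and rng.random() < p_muscle:
                dst = muscles[rng.integers(len(muscles))]
            else:
                dst = neurons[rng.integers(len(neurons))]
                if dst == src:
                    continue
            edges.add((src, dst))
    # guarantee each muscle at least one motor in-edge
    fed = {v for _, v in edges}
    for mus in muscles:
        if mus not in fed and motors:
            edges.add((motors[rng.integers(len(motors))], mus))
    return DirectedNetwork(cats, edges, stage_label=stage_label)


@dataclass(frozen=True)
class GrowthConfig:
    """Schedule for a synthetic developmental series.

    Node and edge counts are interpolated linearly (and rounded) between the
    initial and final values across ``stages`` stages; muscles are present
    from stage 1.  ``edge_jitter`` > 0 perturbs interior stage edge counts
    by up to that fraction, allowing the non-monotone dips real
    developmental data show; with jitter the edge sets are no longer nested.
    """

    stages: int = 8
    initial_neurons: int = 161
    final_neurons: int = 180
    initial_edges: int = 675
    final_edges: int = 1933
    muscle_count: int = 26
    hub_count: int = 6
    hub_out_degree_boost: float = 4.0
    edge_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stages < 1:
            raise ValueError("stages must be >= 1")
        if self.final_neurons < self.initial_neurons:
            raise ValueError("final neuron count below initial")
        if self.final_edges < self.initial_edges:
            raise ValueError("final edge count below initial")
        if not 0 <= self.edge_jitter < 1:
            raise ValueError("edge_jitter must be in [0, 1)")

    def _interp(self, a: int, b: int) -> list[int]:
        if self.stages == 1:
            return [b]
        return [
            round(a + (b - a) * t / (self.stages - 1)) for t in range(self.stages)
        ]

    def neuron_schedule(self) -> list[int]:
        return self._interp(self.initial_neurons, self.final_neurons)

    def edge_schedule(self) -> list[int]:
        return self._interp(self.initial_edges, self.final_edges)


def developmental_series(config: GrowthConfig) -> StageSeries:
    """Generate a growth series of connectomes following ``config``.

    The final-stage cell set is generated first; nodes are then "born"
    stage by stage following the neuron schedule, and edges of a rich
    candidate pool are activated to hit the edge schedule exactly.  Without
    jitter the construction is strictly monotone: nodes(t) ⊆ nodes(t+1) and
    edges(t) ⊆ edges(t+1).
    """
    rng = np.random.default_rng(config.seed)
    n_total_neurons = config.final_neurons
    # pool mean degree: enough headroom that every stage target is reachable
    pool_mean = 3.0 * config.final_edges / max(n_total_neurons, 1)
    pool = random_connectome(
        n_neurons=n_total_neurons,
        n_muscles=config.muscle_count,
        mean_degree=pool_mean,
        n_hubs=config.hub_count,
        hub_boost=config.hub_out_degree_boost,
        seed=int(rng.integers(2**31 - 1)),
    )
    neurons = sorted(pool.nodes - pool.muscles)
    muscles = sorted(pool.muscles)
    birth_order = list(neurons)
    rng.shuffle(birth_order)
    # hubs exist from stage 1: they stand in for command interneurons, which
    # are present throughout development
    hubs = [n for n in birth_order if n.startswith("CIN")]
    birth_order = hubs + [n for n in birth_order if not n.startswith("CIN")]

    n_sched = config.neuron_schedule()
    e_sched = config.edge_schedule()
    if config.edge_jitter > 0:
        e_sched = [
            e
            if t in (0, config.stages - 1)
            else max(1, round(e * (1 + rng.uniform(-config.edge_jitter, config.edge_jitter))))
            for t, e in enumerate(e_sched)
        ]

    pool_edges = sorted(pool.edges)
    rng.shuffle(pool_edges)
    stages = []
    current_edges: list[tuple[str, str]] = []  # insertion-ordered, no dups
    current_set: set[tuple[str, str]] = set()
    for t in range(config.stages):
        alive = set(birth_order[: n_sched[t]]) | set(muscles)
        target_e = e_sched[t]
        if target_e < len(current_set):  # jitter dip: retire newest edges
            while len(current_set) > target_e:
                current_set.discard(current_edges.pop())
        if target_e > len(current_set):
            for edge in pool_edges:
                if len(current_set) >= target_e:
                    break
                u, v = edge
                if edge not in current_set and u in alive and v in alive:
                    current_set.add(edge)
                    current_edges.append(edge)
        if len(current_set) != target_e:
            raise ValueError(
                f"infeasible interpolation: stage {t + 1} needs {target_e} edges "
                f"but only {len(current_set)} candidates exist among alive nodes"
            )
        net = DirectedNetwork(
            {n: pool.category(n) for n in alive},
            set(current_set),
            stage_label=f"stage-{t + 1}",
        )
        stages.append(
            Stage(stage_id=t + 1, network=net, n_nodes=net.n_nodes, n_edges=net.n_edges)
        )
    return StageSeries(stages)
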