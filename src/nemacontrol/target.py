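"""Greedy target control: driving a designated output subset.

Full network control is often unnecessary — locomotion, for instance, needs
only the muscle cells steered.  Output controllability of ``dx/dt = Ax + Bu,
y = Cx`` asks for generic rank m of ``Rout = C·[B, AB, ..., A^(N-1)B]``,
where m is the number of targets.  Unlike global structural controllability
this does not reduce to a single maximum matching, so a layered greedy
heuristic is used:

1. start with the target set as the current layer;
2. match the layer's nodes to their in-neighbours (a bipartite maximum
   matching between predecessors and layer members);
3. layer members left unmatched become drivers; the matched predecessors
   form the next layer (they must in turn be steered, one step further
   upstream);
4. repeat until the layer empties, with a stall rule for cycles and a hard
   cap of N iterations.

A node may serve as matched predecessor at several different depths —
controlling several targets through paths of distinct lengths — but within
one layer each predecessor is matched at most once.  The result is
order-dependent, so several seeded node orderings are tried and the smallest
driver set is kept.  The target set itself is always a valid fallback
(driving every output directly makes CB contain a permuted diagonal block),
which bounds the answer by m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import CellTable, DegenerateNetworkError, DirectedNetwork
from .structural import driver_analysis, maximum_matching

__all__ = ["TargetControlReport", "greedy_target_drivers", "muscle_targets"]

DEFAULT_ORDERINGS = 100


@dataclass(frozen=True)
class TargetControlReport:
    """Driver set for steering a target subset, plus the search metadata.

    ``driver_density`` divides by the *total* network size N (not by the
    number of targets), so values are directly comparable with global
    driver densities on the same network.
    """

    n: int
    targets: tuple[str, ...]
    driver_nodes: tuple[str, ...]
    num_drivers: int
    driver_density: float
    orderings_tried: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.targets)


def _layer_matching(
    pred: dict[str, set[str]], layer: set[str], rank: dict[str, int]
) -> tuple[set[str], dict[str, str]]:
    """Greedy-augmenting maximum matching of layer members to predecessors.

    Returns (unmatched layer members, predecessor -> layer member map).
    Processing order follows ``rank``, which makes the tie-breaks — and thus
    the driver set — a deterministic function of the node ordering.
    """
    order = sorted(layer, key=rank.__getitem__)
    mate_of_pred: dict[str, str] = {}
    mate_of_node: dict[str, str] = {}

    def try_augment(node: str, visited: set[str]) -> bool:
        for p in sorted(pred[node], key=rank.__getitem__):
            if p in visited:
                continue
            visited.add(p)
            if p not in mate_of_pred or try_augment(mate_of_pred[p], visited):
                mate_of_pred[p] = node
                mate_of_node[node] = p
                return True
        return False

    for node in order:
        try_augment(node, set())
    unmatched = {node for node in layer if node not in mate_of_node}
    return unmatched, mate_of_pred


def _greedy_once(
    network: DirectedNetwork, targets: set[str], rank: dict[str, int]
) -> set[str]:
    """One pass of the layered greedy procedure under a fixed node ordering."""
    pred = network.predecessors()
    drivers: set[str] = set()
    layer = set(targets)
    max_iters = network.n_nodes
    for _ in range(max_iters):
        if not layer:
            break
        unmatched, mate_of_pred = _layer_matching(pred, layer, rank)
        drivers |= unmatched
        next_layer = set(mate_of_pred)
        if next_layer == layer:
            # pure cycle: every member feeds the next; break it by driving
            # the lexicographically smallest member directly
            promoted = min(layer)
            drivers.add(promoted)
            next_layer = next_layer - {promoted}
        layer = next_layer
    else:
        drivers |= layer  # iteration cap: drive whatever is left upstream
    return drivers


def greedy_target_drivers(
    network: DirectedNetwork,
    targets,
    orderings: int = DEFAULT_ORDERINGS,
    seed: int = 0,
) -> TargetControlReport:
    """Approximately minimal driver set controlling only ``targets``.

    Runs the layered greedy procedure under ``orderings`` node orderings
    (the first is lexicographic, the rest are seeded random permutations)
    and reports the smallest driver set found.  When the target set is the
    whole network the problem *is* global structural controllability, which
    the maximum matching solves exactly, so that route is taken instead.
    """
    targets = set(targets)
    if not targets:
        raise DegenerateNetworkError("target set must be nonempty")
    missing = targets - network.nodes
    if missing:
        raise KeyError(f"targets not in network: {sorted(missing)}")
    if orderings < 1:
        raise ValueError("orderings must be >= 1")

    n = network.n_nodes
    if targets == network.nodes:
        report = driver_analysis(network)
        drivers = report.driver_nodes if not report.floor_applied else (report.floor_driver,)
        return TargetControlReport(
            n=n,
            targets=tuple(sorted(targets)),
            driver_nodes=tuple(sorted(drivers)),
            num_drivers=report.num_drivers,
            driver_density=report.num_drivers / n,
            orderings_tried=orderings,
            seed=seed,
        )

    names = network.sorted_nodes()
    rng = np.random.default_rng(seed)
    best: set[str] = set(targets)  # trivial candidate: drive every target
    for trial in range(orderings):
        if trial == 0:
            order = names
        else:
            order = [names[i] for i in rng.permutation(len(names))]
        rank = {name: i for i, name in enumerate(order)}
        drivers = _greedy_once(network, targets, rank)
        if len(drivers) < len(best):
            best = drivers
    return TargetControlReport(
        n=n,
        targets=tuple(sorted(targets)),
        driver_nodes=tuple(sorted(best)),
        num_drivers=len(best),
        driver_density=len(best) / n,
        orderings_tried=orderings,
        seed=seed,
    )


def muscle_targets(network: DirectedNetwork, cells: CellTable | None = None) -> frozenset[str]:
    """All nodes annotated as muscles.

    With a cell table the annotation comes from the table (falling back to
    the network's own categories); otherwise the network's categories are
    used directly.  May be empty, e.g. on a neuron-only view.
    """
    if cells is None:
        return network.muscles
    return frozenset(
        name
        for name in network.nodes
        if cells.category(name, default=network.category(name)) == "muscle"
    )
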