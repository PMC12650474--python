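"""Structural controllability via maximum matching.

A directed network with linear dynamics ``dx/dt = A x + B u`` is structurally
controllable when the Kalman rank condition holds for almost every choice of
nonzero weights on the edge pattern of ``A`` and ``B``.  The minimum-input
theorem reduces the question to graph matching: split every node ``i`` into an
out-copy ``i+`` and an in-copy ``i-``, add one bipartite edge ``u+ — v-`` per
directed edge ``u → v``, and compute a maximum matching.  Nodes whose in-copy
is unmatched are the *driver nodes* — they must receive independent external
inputs — and

    Nd = max(N - |M|, 1),        nd = Nd / N,

where ``|M|`` is the matching cardinality.  The ``max(..., 1)`` floor covers
perfect matchings: even a fully matched network needs one input signal.

Driver density ``nd`` is the headline statistic: a small ``nd`` means few
independent inputs suffice, i.e. high controllability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .network import DegenerateNetworkError, DirectedNetwork

__all__ = ["Matching", "ControllabilityReport", "maximum_matching", "driver_analysis"]


@dataclass(frozen=True)
class Matching:
    """A matching of the bipartite out-copy/in-copy representation.

    ``pairs`` maps each matched directed edge ``(u, v)`` meaning out-copy of
    ``u`` is matched to in-copy of ``v``.  No node appears twice on either
    side, and every pair is an edge of the source network.
    """

    pairs: frozenset[tuple[str, str]]

    @property
    def cardinality(self) -> int:
        return len(self.pairs)

    @property
    def matched_out(self) -> frozenset[str]:
        return frozenset(u for u, _ in self.pairs)

    @property
    def matched_in(self) -> frozenset[str]:
        return frozenset(v for _, v in self.pairs)

    def successor_map(self) -> dict[str, str]:
        """Matched successor of each matched-out node (u -> v per pair)."""
        return {u: v for u, v in self.pairs}


@dataclass(frozen=True)
class ControllabilityReport:
    """Result of a driver-node analysis.

    Attributes
    ----------
    n : total node count N.
    num_drivers : Nd, the number of independent input channels required.
    driver_density : nd = Nd / N; in (0, 1], lower means more controllable.
    driver_nodes : the unmatched nodes (empty when a perfect matching exists).
    matching_size : cardinality of the maximum matching.
    floor_applied : True when a perfect matching forced Nd up to 1.
    floor_driver : the deterministically chosen single driver in the floor
        case (lexicographically smallest node), else None.
    shared_signal_nodes : one representative node per cycle of the matching
        decomposition.  These receive the *same* signal as the first input
        channel; without them driverless cycles would be inaccessible.
    """

    n: int
    num_drivers: int
    driver_density: float
    driver_nodes: tuple[str, ...]
    matching_size: int
    floor_applied: bool = False
    floor_driver: str | None = None
    shared_signal_nodes: tuple[str, ...] = field(default=())

    def input_channels(self) -> tuple[frozenset[str], ...]:
        """Attachment pattern of the Nd input channels (columns of B).

        Each driver node gets its own channel.  Cycle representatives from
        the matching decomposition are wired onto the first channel (or onto
        the floor driver's channel) as a shared signal, realising the
        constructive proof of the minimum-input theorem.
        """
        if self.floor_applied:
            support = {self.floor_driver, *self.shared_signal_nodes}
            return (frozenset(support),)
        channels = [frozenset({d}) for d in self.driver_nodes]
        if self.shared_signal_nodes and channels:
            channels[0] = channels[0] | frozenset(self.shared_signal_nodes)
        return tuple(channels)


def _bipartite_graph(network: DirectedNetwork, order: list[str] | None = None):
    """Bipartite out-copy/in-copy graph; node insertion order fixes tie-breaks."""
    if order is None:
        order = network.sorted_nodes()
    g = nx.Graph()
    top = [("out", u) for u in order]
    g.add_nodes_from(top)
    g.add_nodes_from(("in", v) for v in order)
    rank = {u: i for i, u in enumerate(order)}
    for u, v in sorted(network.edges, key=lambda e: (rank[e[0]], rank[e[1]])):
        g.add_edge(("out", u), ("in", v))
    return g, top


def maximum_matching(network: DirectedNetwork, order: list[str] | None = None) -> Matching:
    """Maximum-cardinality matching of the bipartite representation.

    The cardinality is unique; the particular matching depends on the node
    processing order, which defaults to lexicographic so results are
    reproducible run-to-run.
    """
    if network.n_nodes == 0:
        raise DegenerateNetworkError("cannot match an empty network")
    g, top = _bipartite_graph(network, order)
    mate = nx.bipartite.hopcroft_karp_matching(g, top_nodes=top)
    pairs = frozenset(
        (side_u[1], side_v[1])
        for side_u, side_v in mate.items()
        if side_u[0] == "out"
    )
    return Matching(pairs)


def _cycle_representatives(network: DirectedNetwork, matching: Matching) -> tuple[str, ...]:
    """Lexicographically smallest node of each cycle in the matching decomposition.

    Matched edges form vertex-disjoint paths and cycles over the node set;
    nodes on cycles have no unmatched ancestor, so each cycle must be touched
    by an input signal for the system to be accessible.
    """
    succ = matching.successor_map()
    unmatched_in = sorted(network.nodes - matching.matched_in)
    on_path: set[str] = set()
    for start in unmatched_in:  # walk each path from its unmatched head
        node = start
        while node not in on_path:
            on_path.add(node)
            if node not in succ:
                break
            node = succ[node]
    reps = []
    seen: set[str] = set(on_path)
    for node in sorted(succ):
        if node in seen:
            continue
        cycle = []
        cur = node
        while cur not in seen:
            seen.add(cur)
            cycle.append(cur)
            cur = succ[cur]
        if cycle:
            reps.append(min(cycle))
    return tuple(sorted(reps))


def driver_analysis(network: DirectedNetwork) -> ControllabilityReport:
    """Identify driver nodes and the driver density nd of a network.

    Drivers are the in-copies left unmatched by a maximum matching; when the
    matching is perfect the floor ``Nd = 1`` applies and the lexicographically
    smallest node is designated as the single driver.
    """
    matching = maximum_matching(network)
    n = network.n_nodes
    unmatched = tuple(sorted(network.nodes - matching.matched_in))
    floor_applied = len(unmatched) == 0
    num_drivers = max(len(unmatched), 1)
    return ControllabilityReport(
        n=n,
        num_drivers=num_drivers,
        driver_density=num_drivers / n,
        driver_nodes=unmatched,
        matching_size=matching.cardinality,
        floor_applied=floor_applied,
        floor_driver=min(network.nodes) if floor_applied else None,
        shared_signal_nodes=_cycle_representatives(network, matching),
    )
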