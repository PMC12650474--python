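"""Core domain types: directed connectome networks, cell annotations, stage series.

A connectome is modelled as a directed graph over named cells: chemical
synapses contribute one directed edge (pre → post), gap junctions contribute
a reciprocal pair.  Only the topology (the zero/nonzero pattern of the state
matrix ``A``) is retained — structural controllability depends on nothing
else.  Cells carry one of a closed set of category labels so that
neuron-only and cell-level views, muscle target sets, and per-category
ablation summaries can be derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

#: Closed category enumeration for cells.
CATEGORIES = ("sensory", "interneuron", "motor", "muscle", "effector", "other")

#: Categories counted as neurons (the "neural network" view).
NEURON_CATEGORIES = frozenset({"sensory", "interneuron", "motor"})

_CATEGORY_ALIASES = {
    "sensory": "sensory",
    "sensory neuron": "sensory",
    "sensoryneuron": "sensory",
    "inter": "interneuron",
    "interneuron": "interneuron",
    "motor": "motor",
    "motorneuron": "motor",
    "motor neuron": "motor",
    "muscle": "muscle",
    "effector": "effector",
    "other": "other",
    "unknown": "other",
}


class NetworkFormatError(ValueError):
    """Raised when an input file or record does not match the expected layout."""


class DegenerateNetworkError(ValueError):
    """Raised when an operation receives an empty or otherwise degenerate network."""


def normalize_category(raw: str) -> str:
    """Map a free-form category string onto the closed enumeration.

    Case-insensitive; a handful of common synonyms ("inter", "motor neuron")
    are accepted.  Unrecognised values raise :class:`NetworkFormatError`.
    """
    key = str(raw).strip().lower()
    try:
        return _CATEGORY_ALIASES[key]
    except KeyError:
        raise NetworkFormatError(
            f"unknown cell category {raw!r}; expected one of {CATEGORIES}"
        ) from None


@dataclass(frozen=True)
class DirectedNetwork:
    """A directed network of named, categorised cells.

    Parameters
    ----------
    categories :
        Mapping from node name to category (one of :data:`CATEGORIES`).
        The key set defines the node set; names are case-sensitive and
        unique by construction.
    edges :
        Set of ordered ``(source, target)`` pairs.  Parallel edges are
        collapsed; self-loops (autapses) are permitted.
    stage_label :
        Optional free-text label (e.g. a developmental stage).
    """

    categories: Mapping[str, str]
    edges: frozenset[tuple[str, str]]
    stage_label: str | None = None

    def __init__(
        self,
        categories: Mapping[str, str] | Iterable[str],
        edges: Iterable[tuple[str, str]],
        stage_label: str | None = None,
    ) -> None:
        if not isinstance(categories, Mapping):
            categories = {name: "other" for name in categories}
        cats = {}
        for name, cat in categories.items():
            cats[str(name)] = normalize_category(cat)
        edge_set = frozenset((str(u), str(v)) for u, v in edges)
        for u, v in edge_set:
            if u not in cats or v not in cats:
                raise NetworkFormatError(
                    f"edge ({u!r}, {v!r}) references an undeclared node"
                )
        object.__setattr__(self, "categories", dict(cats))
        object.__setattr__(self, "edges", edge_set)
        object.__setattr__(self, "stage_label", stage_label)

    # -- basic accessors -------------------------------------------------
    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.categories)

    @property
    def n_nodes(self) -> int:
        return len(self.categories)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.categories)

    def category(self, name: str) -> str:
        return self.categories[name]

    def nodes_of_category(self, *cats: str) -> frozenset[str]:
        wanted = set(cats)
        return frozenset(n for n, c in self.categories.items() if c in wanted)

    @property
    def neurons(self) -> frozenset[str]:
        return frozenset(
            n for n, c in self.categories.items() if c in NEURON_CATEGORIES
        )

    @property
    def muscles(self) -> frozenset[str]:
        return self.nodes_of_category("muscle")

    # -- derived views ---------------------------------------------------
    def subnetwork(self, keep: Iterable[str], stage_label: str | None = None) -> "DirectedNetwork":
        """Induced subnetwork on ``keep`` (edges with any dropped endpoint removed)."""
        keep = set(keep)
        missing = keep - self.nodes
        if missing:
            raise KeyError(f"nodes not in network: {sorted(missing)}")
        return DirectedNetwork(
            {n: c for n, c in self.categories.items() if n in keep},
            {(u, v) for u, v in self.edges if u in keep and v in keep},
            stage_label if stage_label is not None else self.stage_label,
        )

    def predecessors(self) -> dict[str, set[str]]:
        """In-neighbour map (including self-loops)."""
        pred: dict[str, set[str]] = {n: set() for n in self.categories}
        for u, v in self.edges:
            pred[v].add(u)
        return pred

    def successors(self) -> dict[str, set[str]]:
        succ: dict[str, set[str]] = {n: set() for n in self.categories}
        for u, v in self.edges:
            succ[u].add(v)
        return succ

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for name in self.sorted_nodes():
            g.add_node(name, category=self.categories[name])
        g.add_edges_from(sorted(self.edges))
        return g

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lbl = f", stage={self.stage_label!r}" if self.stage_label else ""
        return f"DirectedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges}{lbl})"


@dataclass(frozen=True)
class CellTable:
    """Cell annotations: unique names mapped to categories, with free-text notes."""

    categories: Mapping[str, str]
    notes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cats = {str(n): normalize_category(c) for n, c in self.categories.items()}
        object.__setattr__(self, "categories", cats)
        object.__setattr__(self, "notes", dict(self.notes))

    def __contains__(self, name: str) -> bool:
        return name in self.categories

    def category(self, name: str, default: str = "other") -> str:
        return self.categories.get(name, default)

    def __len__(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class Stage:
    """One developmental stage: an integer id, a network, and size tallies."""

    stage_id: int
    network: DirectedNetwork
    n_nodes: int
    n_edges: int

    def __post_init__(self) -> None:
        if self.n_nodes != self.network.n_nodes or self.n_edges != self.network.n_edges:
            raise ValueError(
                f"stage {self.stage_id}: recorded tallies ({self.n_nodes} nodes, "
                f"{self.n_edges} edges) disagree with the network "
                f"({self.network.n_nodes}, {self.network.n_edges})"
            )


@dataclass(frozen=True)
class StageSeries:
    """An ordered developmental series of networks with per-stage tallies."""

    stages: tuple[Stage, ...]

    def __init__(self, stages: Sequence[Stage]) -> None:
        stages = tuple(stages)
        ids = [s.stage_id for s in stages]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError(f"stage ids must be strictly increasing, got {ids}")
        object.__setattr__(self, "stages", stages)

    def __iter__(self):
        return iter(self.stages)

    def __len__(self) -> int:
        return len(self.stages)

    def __getitem__(self, i: int) -> Stage:
        return self.stages[i]

    def networks(self) -> list[DirectedNetwork]:
        return [s.network for s in self.stages]
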