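"""Numerical verification of structural (output) controllability.

Structural results claim that a property holds for *almost every* assignment
of weights to the nonzero pattern of (A, B, C).  This module checks such
claims directly on small systems: draw random weights, build the Kalman
controllability matrix

    R = [B, AB, A^2 B, ..., A^(N-1) B]

(or the output controllability matrix ``Rout = C R``), and compute its
numerical rank.  The generic rank is the maximum over weight draws; a
handful of draws recovers it with overwhelming probability because the
failure set has measure zero.

Also provides an exhaustive minimal-driver search used as the exact
reference against the matching and greedy algorithms in the test suite.
Everything here is deliberately capped at small N — it is an oracle, not a
scalable method.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import DirectedNetwork

__all__ = [
    "StructuredSystem",
    "generic_controllable",
    "generic_output_rank",
    "minimal_driver_search",
]

#: Largest state dimension the oracle accepts.
DEFAULT_NODE_CAP = 12
#: Largest network for exhaustive driver-subset enumeration.
DEFAULT_SEARCH_CAP = 8
#: Default number of independent weight draws.
DEFAULT_TRIALS = 5


class OracleCapExceeded(ValueError):
    """The instance is too large for the small-scale oracle."""


@dataclass(frozen=True)
class StructuredSystem:
    """Zero/nonzero patterns of a linear system dx/dt = Ax + Bu, y = Cx.

    ``input_channels`` gives the attachment pattern of each column of B: a
    channel usually drives a single node, but a shared signal may attach to
    several (needed to reach driverless cycles).  ``outputs`` lists the
    target nodes, one row of C each.
    """

    nodes: tuple[str, ...]
    a_edges: frozenset[tuple[str, str]]
    input_channels: tuple[frozenset[str], ...]
    outputs: tuple[str, ...]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        if len(self.nodes) != len(node_set):
            raise ValueError("duplicate node names")
        for u, v in self.a_edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"A-pattern edge ({u}, {v}) off the node set")
        for ch in self.input_channels:
            if not ch or not ch <= node_set:
                raise ValueError("each input channel must attach to existing nodes")
        if not set(self.outputs) <= node_set:
            raise ValueError("outputs must be existing nodes")

    @classmethod
    def from_network(
        cls,
        network: DirectedNetwork,
        drivers: Iterable[str] | Iterable[frozenset[str]],
        targets: Iterable[str] | None = None,
    ) -> "StructuredSystem":
        """Build a system from a network, a driver spec and a target set.

        ``drivers`` may be node names (one single-attachment channel each)
        or explicit attachment sets.  ``targets=None`` means all nodes.
        """
        nodes = tuple(network.sorted_nodes())
        drivers = list(drivers)
        channels = []
        for d in drivers:
            if isinstance(d, str):
                channels.append(frozenset({d}))
            else:
                channels.append(frozenset(d))
        outputs = tuple(sorted(targets)) if targets is not None else nodes
        return cls(nodes, frozenset(network.edges), tuple(channels), outputs)

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def m(self) -> int:
        return len(self.outputs)


def _draw_matrices(system: StructuredSystem, rng: np.random.Generator):
    """One random realisation of (A, B, C); weights uniform on [0.5, 1.5]."""
    idx = {name: i for i, name in enumerate(system.nodes)}
    n = system.n
    a = np.zeros((n, n))
    for u, v in system.a_edges:
        a[idx[v], idx[u]] = rng.uniform(0.5, 1.5)
    b = np.zeros((n, len(system.input_channels)))
    for j, channel in enumerate(system.input_channels):
        for node in channel:
            b[idx[node], j] = rng.uniform(0.5, 1.5)
    c = np.zeros((system.m, n))
    for i, node in enumerate(system.outputs):
        c[i, idx[node]] = rng.uniform(0.5, 1.5)
    return a, b, c


def _controllability_blocks(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Horizontally stacked [B, AB, ..., A^(N-1)B] with per-block rescaling.

    Rescaling a block by a positive scalar leaves its column space (hence the
    rank) unchanged while preventing overflow along long chains.
    """
    n = a.shape[0]
    blocks = [b]
    cur = b
    for _ in range(n - 1):
        cur = a @ cur
        peak = np.abs(cur).max()
        if peak > 0:
            cur = cur / peak
        blocks.append(cur)
    return np.hstack(blocks)


def _numerical_rank(mat: np.ndarray) -> int:
    if mat.size == 0:
        return 0
    s = np.linalg.svd(mat, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    tol = max(mat.shape) * np.finfo(mat.dtype).eps * s[0]
    return int(np.sum(s > tol))


def _check_cap(n: int, cap: int) -> None:
    if n > cap:
        raise OracleCapExceeded(
            f"system has {n} nodes; the numerical oracle is capped at {cap}"
        )


def generic_controllable(
    system: StructuredSystem,
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
    cap: int = DEFAULT_NODE_CAP,
) -> bool:
    """True iff some weight draw satisfies the Kalman rank condition rank(R)=N."""
    _check_cap(system.n, cap)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(trials):
        a, b, _ = _draw_matrices(system, rng)
        if _numerical_rank(_controllability_blocks(a, b)) == system.n:
            return True
    return False


def generic_output_rank(
    system: StructuredSystem,
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
    cap: int = DEFAULT_NODE_CAP,
) -> int:
    """Maximum numerical rank of Rout = C·[B, AB, ...] over weight draws.

    The system is generically output controllable iff the result equals the
    number of outputs m.
    """
    _check_cap(system.n, cap)
    if trials < 1:
        raise ValueError("trials must be >= 1")
    rng = np.random.default_rng(seed)
    best = 0
    for _ in range(trials):
        a, b, c = _draw_matrices(system, rng)
        best = max(best, _numerical_rank(c @ _controllability_blocks(a, b)))
        if best == system.m:
            break
    return best


def minimal_driver_search(
    network: DirectedNetwork,
    targets: Iterable[str] | None = None,
    cap: int = DEFAULT_SEARCH_CAP,
    trials: int = DEFAULT_TRIALS,
    seed: int = 0,
) -> int:
    """Exact minimum number of inputs for generic (output) controllability.

    Global mode (``targets=None``): the smallest number of independent input
    *channels*, each allowed to attach to any nodes (shared signals), that
    achieves full generic rank.  By the minimum-input theorem this equals
    ``max(N - |M|, 1)`` for a maximum matching M, making it an independent
    reference for the matching computation.

    Target mode: the smallest node subset which, with one single-attachment
    channel per node, achieves generic output rank m — the exact reference
    for the greedy target-control heuristic, whose drivers have exactly that
    form.
    """
    n = network.n_nodes
    _check_cap(n, cap)
    names = network.sorted_nodes()
    all_nodes = frozenset(names)
    if targets is None:
        for k in range(1, n + 1):
            channels = tuple(all_nodes for _ in range(k))
            system = StructuredSystem.from_network(network, channels, None)
            if generic_controllable(system, trials=trials, seed=seed, cap=cap):
                return k
        return n  # pragma: no cover - k = n always succeeds
    targets = sorted(set(targets))
    if not set(targets) <= all_nodes:
        raise KeyError(f"targets not in network: {sorted(set(targets) - all_nodes)}")
    m = len(targets)
    if m == 0:
        raise ValueError("target set must be nonempty")
    for k in range(1, n + 1):
        for subset in itertools.combinations(names, k):
            system = StructuredSystem.from_network(network, subset, targets)
            if generic_output_rank(system, trials=trials, seed=seed, cap=cap) == m:
                return k
    return n  # pragma: no cover - driving the targets themselves always works
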