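# Methods

## Model

A connectome is a directed graph over named, categorised cells (sensory,
interneuron, motor, muscle, effector, other).  Chemical synapses give one
directed edge pre → post; gap junctions, being electrical and effectively
bidirectional, are encoded as a reciprocal pair of directed edges.  Synapse
counts and weights are parsed but discarded: every analysis here is
structural, i.e. a statement about the zero/nonzero pattern of the linear
system

    dx/dt = A x + B u,    y = C x

that holds for almost every assignment of nonzero weights.  Parallel edges
collapse on load; self-loops (autapses) are kept by default because a
self-loop is a matchable edge, and can be dropped with a dialect flag.
Two node universes are distinguished throughout: the *cell network* (all
loaded cells) and the *neural network* (the induced subnetwork on the three
neuron categories).

## Global controllability

By the minimum-input theorem, the minimum number of independent input
signals for generic controllability is `Nd = max(N − |M|, 1)`, where `M` is
a maximum matching of the bipartite out-copy/in-copy representation of the
graph.  The unmatched in-copies are the driver nodes.  The matching is
computed with the Hopcroft–Karp algorithm (networkx) over nodes processed
in lexicographic order, so driver *sets* are reproducible run to run; only
the cardinality is invariant across implementations, and the test suite
checks that invariance against scipy's independent csgraph matcher and a
numerical rank oracle.

Two details follow the constructive proof of the theorem rather than the
bare matching count:

* **Perfect-matching floor.** When `N = |M|`, one input is still required;
  the report flags `floor_applied` and designates the lexicographically
  smallest node as the single driver.
* **Shared-signal attachments.** The matched edges decompose the node set
  into paths and cycles.  Nodes on driverless cycles are inaccessible from
  the unmatched drivers through matched edges alone, so the report records
  one representative (lexicographically smallest) node per cycle; these are
  wired onto the first input channel as a *shared* signal.  The resulting
  channel pattern (`ControllabilityReport.input_channels()`) is what passes
  the numerical Kalman-rank check in every sampled case; a bare
  one-node-per-driver B does not, e.g. on a graph consisting of a path plus
  a disjoint two-cycle.

`nd = Nd / N` is the headline statistic; lower is more controllable.

## Target control

Steering only a target subset (typically the muscles) asks for generic rank
m of `Rout = C·[B, AB, …, Aⁿ⁻¹B]`.  This does not reduce to one matching,
so an approximate layered greedy search is used: the current layer
(initially the targets) is matched to its in-neighbours with a greedy
augmenting-path matching; unmatched layer members become drivers; matched
predecessors form the next layer, one step upstream.  A node may serve as
matched predecessor at several distinct depths — that corresponds to
controlling several targets through paths of different lengths — but within
one layer each predecessor is used once.  Termination: the layer empties,
or a stall rule fires when the next layer equals the current one (a pure
cycle; the lexicographically smallest member is promoted to driver), with a
hard cap of N iterations after which the remaining layer is driven
directly.

The outcome is ordering-dependent, so `orderings` node permutations are
tried (the first is lexicographic, the rest drawn from the seeded
generator; the seed is recorded in the report) and the smallest driver set
wins.  The target set itself is always kept as a fallback candidate —
driving every output directly is trivially output controllable — which
bounds the result by m.  When the target set is the entire node set the
problem *is* global controllability and is answered exactly by the
matching.  Reported `nd` divides by the total network size N, not by m, so
global and targeted densities are directly comparable (and match the
convention of published stage tables, e.g. 26 drivers on a 187-cell network
→ 0.139).

On networks small enough for enumeration, every greedy driver set is
certified by the output-rank oracle, and comparison against the exhaustive
minimum shows the heuristic exact on the large majority of random instances
(the acceptance suite measures the rate; it asserts validity always and
majority-exactness).

## Numerical rank oracle

The oracle draws independent weights uniform on [0.5, 1.5] (sign-free; the
failure set of generic statements has measure zero, so signs are
irrelevant) for every pattern entry of A, B, C, builds the controllability
blocks by repeated multiplication with per-block sup-norm rescaling
(rescaling a block changes no rank and prevents overflow on long chains),
and takes the numerical rank via SVD with the standard tolerance
`max(dim) · eps · σ₁`.  Defaults: 5 draws, generic rank as the maximum over
draws; deterministic given (trials, seed).  Caps: 12 nodes for rank checks,
8 for exhaustive search — it is an oracle for tests and the `verify`
subcommand, not a scalable method.

`minimal_driver_search` has two modes.  Global mode minimises the number of
independent input *channels*, each allowed to attach anywhere (free
support): that is the quantity the minimum-input theorem equates with
`max(N − |M|, 1)`, making the search an independent reference for the
matching implementation.  Target mode enumerates node subsets with one
single-attachment channel per node, in increasing size — the exact
reference for the greedy heuristic, whose driver sets have exactly that
form.

## Ablation

Each node is removed in turn (with all incident edges) and the driver
density of the remaining (N−1)-node network recomputed; the influence score
is `nd_after − nd_baseline`, so positive influence means the removal
degraded controllability.  The profile is deterministic, bounded by
`[1/(N−1) − nd, 1 − nd]`, assigns equal scores to automorphic nodes, and
aggregates by category.  Ablation defaults to the neural view (neurons are
what one lesions); cell-level ablation is a flag away.  On adult
*C. elegans* data the expectation — documented, not unit-tested, because it
depends on external files — is that the command interneurons AVAL/AVAR,
AVBL/AVBR, AVEL/AVER occupy the top influence tier and interneurons as a
class outrank motor and sensory neurons; the desk-scale counterpart
asserted in tests is that the synthetic generator's labelled hubs outscore
the remaining neurons on average.

## Synthetic data generator

The generator emulates the structural features the analysis is sensitive
to, at the scale of the developmental connectome series it stands in for:

* default growth series: 8 stages, 161 → 180 neurons and 675 → 1933
  directed connections (linear interpolation, rounded), with a fixed
  complement of 26 muscle cells present from stage 1;
* right-skewed out-degrees from a truncated geometric law with target mean
  total degree 8 (≈ 2 500 draws at adult scale), with 6 designated hub
  interneurons (`CIN01`…) whose out-degree is boosted ×4 — stand-ins for
  command interneurons, present from stage 1;
* muscles are pure sinks; motor neurons route about half their output to
  muscles, other neurons 2%, and every muscle is guaranteed at least one
  motor in-edge so target control is well posed.

Growth is strictly monotone — nodes(t) ⊆ nodes(t+1), edges(t) ⊆ edges(t+1),
with per-stage counts hitting the interpolation schedule exactly — unless
`edge_jitter` is set, which perturbs interior edge counts to allow the
small non-monotone dips real series show (nested edge sets are then no
longer guaranteed; node growth stays monotone).  Everything is a
deterministic function of the seed.

What the generator does **not** emulate: cell birth lineages and timing,
spatial/bilateral structure, synapse weights and multiplicity, the specific
degree sequence or community structure of a real connectome.  Passing tests
therefore demonstrate correctness of the algorithms and the qualitative
hub/target structure, not biological claims about any particular nervous
system.

## Design choices on genuinely open points

* Gap junctions as reciprocal directed edge pairs, unweighted and
  unthresholded: source data conventions differ and no encoding is
  canonical; this is the least-committal choice that keeps the matrix
  pattern symmetric for electrical coupling.
* Driver-set tie-breaks are lexicographic everywhere, so reports are
  byte-identical across runs; no claim is made that the particular driver
  set is unique, only that Nd and nd are.
* Greedy defaults: 100 orderings, seed recorded in every report.
* Edgeless networks give nd = 1 (every node its own driver); empty networks
  and empty target sets are rejected as degenerate rather than given a
  convention.
* Problem sizes in the test and acceptance suites: 200 random digraphs on
  ≤ 5 nodes for the exact global cross-check, 100 instances on ≤ 8 nodes
  for target control, 50 generator seeds at the default 200-cell scale for
  the pipeline invariants — chosen as the smallest sizes at which the
  enumeration oracles are still exact and the sampled space is diverse.

## Known limitations

* The greedy target-control result is an upper bound on the true minimum;
  exactness is only certified at oracle scale.
* Structural statements are generic: a real network with tuned weights can
  in principle be less controllable than the structural count suggests.
* Influence scores are single-node; pairwise or edge ablation is out of
  scope, as are control-energy metrics and input-placement costs.
* The pipeline reports N for every normalisation it prints, because
  published driver densities are ambiguous when the node universe (cells
  vs neurons vs neurons-plus-targets) is not stated alongside them.
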