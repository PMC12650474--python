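# nemacontrol

Controllability analysis of directed connectomes — driver-node
identification, target control of effector subsets, and single-neuron
ablation influence — built for developmental series of *C. elegans*-scale
nervous systems (hundreds of cells, a few thousand synapses), and fully
runnable offline through a synthetic connectome generator.

## The science

Treat each cell as a state node and each synapse as a directed edge: a
chemical synapse is one edge pre → post, a gap junction a reciprocal pair.
The network's linear dynamics are

    dx/dt = A x + B u,        y = C x,

where the pattern of **A** is the wiring diagram, **B** places external
inputs, and **C** reads out designated targets (e.g. muscles).  The system
is controllable when the Kalman matrix
`R = [B, AB, A²B, …, Aⁿ⁻¹B]` has full rank N, and *output* controllable
when `Rout = C·R` has rank m (the number of targets).  Because synaptic
weights are unknown, the analysis is *structural*: what holds for almost
every weight assignment consistent with the wiring.

Structural controllability reduces to maximum matching.  Split each node
into an out-copy and an in-copy, put one bipartite edge per synapse, and
take a maximum matching **M**: the nodes whose in-copy stays unmatched are
the **driver nodes** — they need independent inputs — and

    Nd = max(N − |M|, 1),        nd = Nd / N.

A small driver density `nd` means few inputs steer everything: a directed
path of four nodes needs one driver (`nd = 0.25`, high controllability),
while a four-node star needs three (`nd = 0.75`, low).  Target control of a
subset (the muscles) does not reduce to one matching; a layered greedy
matching walks upstream from the targets, promotes unmatched layer members
to drivers, tries many node orderings, and certifies results on small
instances with the `Rout` rank condition.  Ablation influence is the rise
in `nd` when one node is deleted — command-interneuron-like hubs score
highest.

## Worked example

Generate an eight-stage synthetic developmental series (161→180 neurons,
675→1933 directed connections, 26 muscles, 6 hub interneurons) and analyse
the final stage:

```sh
nemacontrol simulate --stages 8 --seed 0 --out demo
nemacontrol analyze --edges demo/stage8_edges.csv \
                    --cells demo/stage8_cells.csv \
                    --orderings 50 --seed 0 --out demo/run
```

which prints

```
N=206 Nd=45 nd=0.2184
```

— of the 206 cells at the adult-like stage, 45 must receive independent
inputs for full cell-level control (driver density 0.2184).  The JSON
reports in `demo/run/` add the neuron-only view (Nd = 23 of 180,
nd = 0.1278 — the neural network is easier to steer than the full cell
network) and muscle-target control (Nd = 24, nd = 0.1165 — steering just
the 26 muscles needs about half the drivers that full control does).

The same API is available in Python:

```python
from nemacontrol import driver_analysis, greedy_target_drivers, path_network

report = driver_analysis(path_network(4))     # Nd=1, nd=0.25
tc = greedy_target_drivers(path_network(4), {"3", "4"}, orderings=10, seed=0)
print(report.driver_density, tc.num_drivers)  # 0.25 1
```

Other subcommands: `series` (cross-stage table from a YAML config),
`compare` (two-connectome, e.g. hermaphrodite vs male, side-by-side),
`ablate` (per-node influence CSV), `verify` (numerical Kalman-rank check of
a driver set on small networks).

## Layout

| module | purpose |
| --- | --- |
| `nemacontrol.network` | `DirectedNetwork`, `CellTable`, `StageSeries` types |
| `nemacontrol.io` | edge-list/cell-table readers, report writers, neural view |
| `nemacontrol.structural` | maximum matching, driver analysis (`Nd`, `nd`) |
| `nemacontrol.target` | greedy target control, muscle target sets |
| `nemacontrol.oracle` | numerical Kalman-rank verification, exact small-instance search |
| `nemacontrol.ablation` | single-node removal influence profiles |
| `nemacontrol.synthetic` | toy topologies, random connectomes, growth series |
| `nemacontrol.pipeline` / `nemacontrol.cli` | per-stage and cross-stage orchestration |

See `docs/methods.md` for the model, algorithmic details, parameter
defaults and limitations.
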