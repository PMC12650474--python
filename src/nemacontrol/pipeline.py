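"""Per-stage and cross-stage controllability analyses.

A "stage" is one connectome snapshot.  For each stage the pipeline computes
three complementary quantities:

* cell-network controllability — driver analysis over every cell (neurons
  plus muscles and other effectors);
* neural-network controllability — driver analysis over the neuron-only
  induced subnetwork;
* muscle-target controllability — the greedy target-control driver set for
  the muscle cells, normalised by the cell-network size.

Cross-stage runs stack these into one row per stage, the shape in which
developmental trajectories (and the hermaphrodite/male comparison) are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import io as cio
from .network import CellTable, DegenerateNetworkError, DirectedNetwork, StageSeries
from .structural import ControllabilityReport, driver_analysis
from .target import DEFAULT_ORDERINGS, TargetControlReport, greedy_target_drivers, muscle_targets

__all__ = ["StageReport", "analyze_stage", "run_stage", "run_series", "compare_sexes"]

logger = logging.getLogger("nemacontrol")


@dataclass(frozen=True)
class StageReport:
    """All controllability analyses for one connectome snapshot."""

    label: str
    n_cells: int
    n_cell_edges: int
    n_neurons: int
    n_neural_edges: int
    cell_report: ControllabilityReport
    neural_report: ControllabilityReport | None
    muscle_report: TargetControlReport | None

    def to_row(self) -> dict:
        row = {
            "stage": self.label,
            "n_cells": self.n_cells,
            "n_cell_edges": self.n_cell_edges,
            "n_neurons": self.n_neurons,
            "n_neural_edges": self.n_neural_edges,
            "Nd_cell": self.cell_report.num_drivers,
            "nd_cell": self.cell_report.driver_density,
        }
        if self.neural_report is not None:
            row["Nd_neural"] = self.neural_report.num_drivers
            row["nd_neural"] = self.neural_report.driver_density
        if self.muscle_report is not None:
            row["Nd_muscle"] = self.muscle_report.num_drivers
            row["nd_muscle"] = self.muscle_report.driver_density
        return row


def analyze_stage(
    network: DirectedNetwork,
    cells: CellTable | None = None,
    targets: Sequence[str] | None = None,
    orderings: int = DEFAULT_ORDERINGS,
    seed: int = 0,
    label: str | None = None,
) -> StageReport:
    """Run cell-level, neural-level and muscle-target analyses on one network.

    ``targets`` overrides the default muscle target set; when the resolved
    target set is empty the target analysis is skipped, and when the network
    has no neuron-category cells the neural analysis is skipped.
    """
    if cells is not None:
        network = cio.annotate(network, cells)
    label = label or network.stage_label or "stage"
    neurons = network.neurons
    neural_edges = sum(1 for u, v in network.edges if u in neurons and v in neurons)
    logger.info(
        "%s: %d cells, %d edges (%d neurons, %d neural edges)",
        label, network.n_nodes, network.n_edges, len(neurons), neural_edges,
    )

    cell_report = driver_analysis(network)
    try:
        neural_report = driver_analysis(cio.neural_view(network))
    except DegenerateNetworkError:
        neural_report = None

    target_set = set(targets) if targets is not None else set(muscle_targets(network))
    muscle_report = (
        greedy_target_drivers(network, target_set, orderings=orderings, seed=seed)
        if target_set
        else None
    )
    return StageReport(
        label=label,
        n_cells=network.n_nodes,
        n_cell_edges=network.n_edges,
        n_neurons=len(neurons),
        n_neural_edges=neural_edges,
        cell_report=cell_report,
        neural_report=neural_report,
        muscle_report=muscle_report,
    )


def run_stage(
    edges_path: str | Path,
    cells_path: str | Path | None = None,
    dialect: cio.EdgeListDialect = cio.EdgeListDialect(),
    **kwargs,
) -> StageReport:
    """File-based wrapper around :func:`analyze_stage`."""
    cells = cio.read_cell_table(cells_path) if cells_path else None
    network, warnings = cio.read_edge_list(edges_path, dialect, cells)
    for w in warnings:
        logger.warning("%s: %s", edges_path, w)
    return analyze_stage(network, label=kwargs.pop("label", Path(edges_path).stem), **kwargs)


def run_series(
    stages: StageSeries | Sequence[DirectedNetwork],
    orderings: int = DEFAULT_ORDERINGS,
    seed: int = 0,
    fail_fast: bool = True,
) -> pd.DataFrame:
    """One row of controllability results per stage.

    With ``fail_fast=False`` a failing stage is logged and recorded as a row
    of NaNs while the remaining stages still run.
    """
    networks: list[tuple[str, DirectedNetwork]] = []
    if isinstance(stages, StageSeries):
        for s in stages:
            networks.append((s.network.stage_label or f"stage-{s.stage_id}", s.network))
    else:
        for i, net in enumerate(stages, start=1):
            networks.append((net.stage_label or f"stage-{i}", net))
    if not networks:
        raise ValueError("need at least one stage")

    rows = []
    for label, net in networks:
        try:
            rows.append(analyze_stage(net, orderings=orderings, seed=seed, label=label).to_row())
        except Exception:
            if fail_fast:
                raise
            logger.exception("stage %s failed; continuing", label)
            rows.append({"stage": label})
    return pd.DataFrame(rows)


def compare_sexes(
    hermaphrodite: DirectedNetwork,
    male: DirectedNetwork,
    orderings: int = DEFAULT_ORDERINGS,
    seed: int = 0,
) -> pd.DataFrame:
    """Side-by-side neural and muscle-target controllability for two sexes.

    Rows: Nd/nd of the neural network and of the muscle-target analysis;
    N rows make the normalisation universe explicit for each column.
    """
    table = {}
    for name, net in (("hermaphrodite", hermaphrodite), ("male", male)):
        report = analyze_stage(net, label=name, orderings=orderings, seed=seed)
        neural = report.neural_report
        muscle = report.muscle_report
        table[name] = {
            "N_cells": report.n_cells,
            "N_neurons": report.n_neurons,
            "Nd_neural": neural.num_drivers if neural else float("nan"),
            "nd_neural": neural.driver_density if neural else float("nan"),
            "Nd_muscle_target": muscle.num_drivers if muscle else float("nan"),
            "nd_muscle_target": muscle.driver_density if muscle else float("nan"),
        }
    return pd.DataFrame(table)
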