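"""Reading and writing connectome edge lists, cell tables and reports.

Edge lists are CSV/TSV files with a header; the column mapping is
configurable through :class:`EdgeListDialect` (defaults: ``pre``, ``post``,
``type``, ``count``).  Chemical synapse rows become one directed edge
pre → post; gap-junction rows, being electrical and bidirectional, become a
reciprocal pair.  Parallel edges collapse; synapse counts/weights are parsed
but discarded — the controllability analysis is purely structural.

Reports serialise to JSON (nested) or CSV (flat); round-trips are lossless.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .ablation import AblationProfile, AblationRecord
from .network import (
    CellTable,
    DegenerateNetworkError,
    DirectedNetwork,
    NEURON_CATEGORIES,
    NetworkFormatError,
    StageSeries,
)
from .structural import ControllabilityReport
from .target import TargetControlReport

__all__ = [
    "EdgeListDialect",
    "read_edge_list",
    "read_cell_table",
    "annotate",
    "neural_view",
    "write_edge_list",
    "write_cell_table",
    "write_report",
    "read_controllability_report",
    "read_target_report",
    "series_summary",
]


@dataclass(frozen=True)
class EdgeListDialect:
    """Column mapping and options for edge-list files.

    ``type_column=None`` treats every row as a chemical synapse.  Type
    values are matched case-insensitively; ``chemical``/``chem`` and
    ``gap``/``electrical`` are recognised.  ``aliases`` renames cells on
    load (connectome files differ in naming conventions), and
    ``drop_self_loops`` removes autapses, which are otherwise kept.
    """

    source_column: str = "pre"
    target_column: str = "post"
    type_column: str | None = "type"
    weight_column: str | None = "count"
    aliases: dict[str, str] | None = None
    drop_self_loops: bool = False

    def rename(self, name: str) -> str:
        if self.aliases:
            return self.aliases.get(name, name)
        return name


_CHEMICAL = {"chemical", "chem", "send", "synapse"}
_GAP = {"gap", "gapjunction", "gap junction", "gap_junction", "electrical", "ej"}


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)


def read_edge_list(
    path: str | Path,
    dialect: EdgeListDialect = EdgeListDialect(),
    cells: CellTable | None = None,
) -> tuple[DirectedNetwork, list[str]]:
    """Load a connectome edge list into a :class:`DirectedNetwork`.

    Returns the network and a list of warnings (cells appearing in edges but
    absent from the annotation table; they are created with category
    "other").  Raises :class:`NetworkFormatError` on missing columns or
    unrecognised synapse types.
    """
    df = _read_table(path)
    needed = [dialect.source_column, dialect.target_column]
    if dialect.type_column is not None:
        needed.append(dialect.type_column)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise NetworkFormatError(
            f"{path}: missing columns {missing}; found {list(df.columns)}"
        )

    edges: set[tuple[str, str]] = set()
    names: set[str] = set()
    kinds = (
        df[dialect.type_column].tolist()
        if dialect.type_column is not None
        else ["chemical"] * len(df)
    )
    for u_raw, v_raw, kind_raw in zip(
        df[dialect.source_column], df[dialect.target_column], kinds
    ):
        u = dialect.rename(str(u_raw).strip())
        v = dialect.rename(str(v_raw).strip())
        kind = str(kind_raw).strip().lower()
        names.update((u, v))
        if kind in _CHEMICAL:
            edges.add((u, v))
        elif kind in _GAP:
            edges.add((u, v))
            edges.add((v, u))
        else:
            raise NetworkFormatError(f"{path}: unknown synapse type {kind!r}")
    if dialect.drop_self_loops:
        edges = {(u, v) for u, v in edges if u != v}

    warnings: list[str] = []
    categories: dict[str, str] = {}
    for name in sorted(names):
        if cells is not None and name in cells:
            categories[name] = cells.category(name)
        else:
            categories[name] = "other"
            if cells is not None:
                warnings.append(f"cell {name!r} not in annotation table; set to 'other'")
    return DirectedNetwork(categories, edges), warnings


def read_cell_table(path: str | Path) -> CellTable:
    """Load cell annotations (columns ``name``, ``category``, optional ``notes``)."""
    df = _read_table(path)
    for col in ("name", "category"):
        if col not in df.columns:
            raise NetworkFormatError(f"{path}: cell table needs a '{col}' column")
    names = [str(n).strip() for n in df["name"]]
    if len(names) != len(set(names)):
        raise NetworkFormatError(f"{path}: duplicate cell names")
    notes = (
        {n: str(t) for n, t in zip(names, df["notes"])} if "notes" in df.columns else {}
    )
    return CellTable(dict(zip(names, df["category"])), notes)


def annotate(network: DirectedNetwork, cells: CellTable) -> DirectedNetwork:
    """Re-label the network's nodes with categories from a cell table."""
    return DirectedNetwork(
        {n: cells.category(n, default=network.category(n)) for n in network.nodes},
        network.edges,
        network.stage_label,
    )


def neural_view(
    network: DirectedNetwork, cells: CellTable | None = None
) -> DirectedNetwork:
    """Induced subnetwork on neurons only (sensory, interneuron, motor).

    Muscles, other effectors and unknown cells are dropped along with every
    edge touching them.  Idempotent.  Raises on an empty result.
    """
    if cells is not None:
        network = annotate(network, cells)
    keep = {n for n in network.nodes if network.category(n) in NEURON_CATEGORIES}
    if not keep:
        raise DegenerateNetworkError("neural view is empty: no neuron-category cells")
    return network.subnetwork(keep)


# -- writers -----------------------------------------------------------------


def write_edge_list(network: DirectedNetwork, path: str | Path) -> None:
    """Write the network as a chemical-synapse edge list (CSV: pre,post,type,count)."""
    rows = [
        {"pre": u, "post": v, "type": "chemical", "count": 1}
        for u, v in sorted(network.edges)
    ]
    pd.DataFrame(rows, columns=["pre", "post", "type", "count"]).to_csv(
        path, index=False
    )


def write_cell_table(network: DirectedNetwork, path: str | Path) -> None:
    rows = [
        {"name": n, "category": network.category(n)} for n in network.sorted_nodes()
    ]
    pd.DataFrame(rows, columns=["name", "category"]).to_csv(path, index=False)


def _report_dict(report) -> dict:
    d = dataclasses.asdict(report)
    d["__type__"] = type(report).__name__
    return d


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialise a report to JSON (nested) or CSV (flat).

    CSV is available for :class:`AblationProfile` (one row per node) and
    :class:`StageSeries` (one row of tallies per stage); every report type
    supports JSON.
    """
    path = Path(path)
    fmt = format.lower()
    if fmt == "json":
        if isinstance(report, StageSeries):
            payload = {
                "__type__": "StageSeries",
                "stages": [
                    {
                        "stage_id": s.stage_id,
                        "n_nodes": s.n_nodes,
                        "n_edges": s.n_edges,
                        "stage_label": s.network.stage_label,
                    }
                    for s in report
                ],
            }
        else:
            payload = _report_dict(report)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=list))
    elif fmt == "csv":
        if isinstance(report, AblationProfile):
            report.to_dataframe().to_csv(path, index=False)
        elif isinstance(report, StageSeries):
            series_summary(report).to_csv(path, index=False)
        elif isinstance(report, pd.DataFrame):
            report.to_csv(path, index=False)
        else:
            raise ValueError(f"no CSV layout for {type(report).__name__}")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_controllability_report(path: str | Path) -> ControllabilityReport:
    d = json.loads(Path(path).read_text())
    return ControllabilityReport(
        n=d["n"],
        num_drivers=d["num_drivers"],
        driver_density=d["driver_density"],
        driver_nodes=tuple(d["driver_nodes"]),
        matching_size=d["matching_size"],
        floor_applied=d["floor_applied"],
        floor_driver=d["floor_driver"],
        shared_signal_nodes=tuple(d["shared_signal_nodes"]),
    )


def read_target_report(path: str | Path) -> TargetControlReport:
    d = json.loads(Path(path).read_text())
    return TargetControlReport(
        n=d["n"],
        targets=tuple(d["targets"]),
        driver_nodes=tuple(d["driver_nodes"]),
        num_drivers=d["num_drivers"],
        driver_density=d["driver_density"],
        orderings_tried=d["orderings_tried"],
        seed=d["seed"],
    )


def series_summary(series: StageSeries) -> pd.DataFrame:
    """Per-stage node/edge tallies, one row per stage (Table-1-style)."""
    rows = []
    for s in series:
        net = s.network
        neurons = net.neurons
        rows.append(
            {
                "stage": s.stage_id,
                "n_cells": net.n_nodes,
                "n_cell_edges": net.n_edges,
                "n_neurons": len(neurons),
                "n_neural_edges": sum(
                    1 for u, v in net.edges if u in neurons and v in neurons
                ),
            }
        )
    return pd.DataFrame(rows)
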