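"""File output and round-trip readers.

Everything numeric is serialized at 12 significant digits so reruns of the
same seed produce byte-identical files (and therefore stable checksums).
Network snapshots are written both as plain edge-list CSV and as GraphML
with per-node belief attributes.
"""

from __future__ import annotations

import csv
from typing import Optional

import networkx as nx
import pandas as pd

from .metrics import MetricsSeries

__all__ = [
    "FLOAT_FORMAT",
    "write_metrics_csv",
    "write_summary_csv",
    "write_final_states_csv",
    "write_edgelist_csv",
    "write_graphml",
    "read_final_states_csv",
    "read_edgelist_csv",
    "read_graphml",
]

FLOAT_FORMAT = "%.12g"


def write_metrics_csv(metrics: MetricsSeries, path: str, replicate: Optional[int] = None) -> None:
    """Tidy per-step metrics: columns step, metric, value[, replicate]."""
    metrics.to_tidy(replicate).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_summary_csv(summary: pd.DataFrame, path: str) -> None:
    """Replicate summary (step, metric, mean, lo95, hi95)."""
    summary.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_final_states_csv(final_states: pd.DataFrame, path: str) -> None:
    final_states.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_final_states_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_edgelist_csv(graph: nx.Graph, path: str, step: int) -> None:
    """Edge list with columns source, target, step."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "step"])
        for a, b in sorted((min(e), max(e)) for e in graph.edges):
            writer.writerow([a, b, step])


def read_edgelist_csv(path: str) -> nx.Graph:
    df = pd.read_csv(path)
    g = nx.Graph()
    g.add_edges_from(zip(df["source"].astype(int), df["target"].astype(int)))
    return g


def write_graphml(graph: nx.Graph, path: str) -> None:
    g = nx.Graph(**{k: v for k, v in graph.graph.items()})
    g.add_nodes_from(graph.nodes(data=True))
    g.add_edges_from(graph.edges)
    for _, data in g.nodes(data=True):
        for key, value in list(data.items()):
            if isinstance(value, float):
                data[key] = float(FLOAT_FORMAT % value)
    nx.write_graphml(g, path)


def read_graphml(path: str) -> nx.Graph:
    g = nx.read_graphml(path)
    return nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
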