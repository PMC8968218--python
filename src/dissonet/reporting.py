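"""Output writers: CSV tables, GraphML and DOT graph exports."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .effects import MixedGraph
from .ggm import PartialCorrelationNetwork

__all__ = [
    "write_network_csv",
    "write_edge_list",
    "write_network_graphml",
    "write_network_dot",
    "write_mixed_graph_graphml",
    "write_mixed_graph_dot",
]


def write_network_csv(net: PartialCorrelationNetwork, path) -> None:
    pd.DataFrame(net.weights, index=net.labels, columns=net.labels).to_csv(path)


def write_edge_list(net: PartialCorrelationNetwork, path) -> None:
    rows = []
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0.0:
                rows.append({"node1": net.labels[i], "node2": net.labels[j], "weight": w})
    pd.DataFrame(rows, columns=["node1", "node2", "weight"]).to_csv(path, index=False)


def write_network_graphml(net: PartialCorrelationNetwork, path) -> None:
    nx.write_graphml(net.to_graph(), path)


def _dot_escape(s: str) -> str:
    return s.replace('"', r"\"")


def write_network_dot(net: PartialCorrelationNetwork, path) -> None:
    lines = ["graph partial_correlations {"]
    for v in net.labels:
        lines.append(f'  "{_dot_escape(v)}";')
    for i in range(net.p):
        for j in range(i + 1, net.p):
            w = net.weights[i, j]
            if w != 0.0:
                color = "blue" if w > 0 else "red"
                lines.append(
                    f'  "{_dot_escape(net.labels[i])}" -- "{_dot_escape(net.labels[j])}"'
                    f' [weight={abs(w):.4f}, color={color}, label="{w:.3f}"];'
                )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_mixed_graph_graphml(g: MixedGraph, path) -> None:
    G = g.to_graph()
    for u, v, d in G.edges(data=True):
        for k, val in list(d.items()):
            if isinstance(val, float) and np.isnan(val):
                d[k] = -1.0
    nx.write_graphml(G, path)


def write_mixed_graph_dot(g: MixedGraph, path) -> None:
    lines = ["digraph posterior_mixed_graph {"]
    for v in g.nodes:
        lines.append(f'  "{_dot_escape(v)}";')
    for u, v in g.directed_edges:
        key = (u, v) if (u, v) in g.inclusion_freq else (v, u)
        lines.append(
            f'  "{_dot_escape(u)}" -> "{_dot_escape(v)}"'
            f' [label="{g.inclusion_freq[key]:.2f}/{g.direction_freq[(u, v)]:.2f}"];'
        )
    for u, v in g.undirected_edges:
        key = (u, v) if (u, v) in g.inclusion_freq else (v, u)
        lines.append(
            f'  "{_dot_escape(u)}" -> "{_dot_escape(v)}"'
            f' [dir=none, label="{g.inclusion_freq[key]:.2f}"];'
        )
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
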