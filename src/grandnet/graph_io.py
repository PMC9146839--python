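"""Edge-list / attribute readers and writers.

The canonical interchange format is a two-column TSV of node labels:
'#'-prefixed comment lines and blank lines are ignored, each undirected
edge appears once.  Labels are opaque strings externally and contiguous
integer indices internally; writers emit the canonical form (labels sorted
lexicographically, endpoints of each edge sorted, edges sorted).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .network import GraphValidationError, NetworkState


class EdgeListParseError(ValueError):
    """Malformed edge-list input; the message names the offending line."""


def read_edge_list(path) -> tuple[NetworkState, list[str]]:
    """Parse a TSV edge list; returns the graph and the sorted label list.

    The node set is the set of labels appearing in edges; an empty file
    yields the empty graph on zero nodes.  Duplicate edges and self-loops
    are rejected with their line numbers.
    """
    raw_edges: list[tuple[str, str, int]] = []
    labels: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) == 1:
                parts = stripped.split()
            if len(parts) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected two node labels, got {len(parts)} fields"
                )
            u, v = parts
            if u == v:
                raise EdgeListParseError(f"{path}:{lineno}: self-loop at label {u!r}")
            raw_edges.append((u, v, lineno))
            labels.update((u, v))
    ordered = sorted(labels)
    index = {lab: i for i, lab in enumerate(ordered)}
    state = NetworkState(len(ordered))
    for u, v, lineno in raw_edges:
        try:
            state.add_edge(index[u], index[v])
        except GraphValidationError:
            raise EdgeListParseError(
                f"{path}:{lineno}: duplicate edge between {u!r} and {v!r}"
            ) from None
    return state, ordered


def write_edge_list(state: NetworkState, path, labels: list[str] | None = None) -> None:
    """Write the canonical TSV edge list (one undirected edge per line)."""
    if labels is None:
        width = len(str(max(state.N - 1, 0)))
        labels = [f"n{i:0{width}d}" for i in range(state.N)]
    if len(labels) != state.N:
        raise ValueError("need one label per node")
    rows = sorted(tuple(sorted((labels[i], labels[j]))) for i, j in state.edges)
    with open(path, "w") as fh:
        fh.write("# undirected simple graph, one edge per line\n")
        for u, v in rows:
            fh.write(f"{u}\t{v}\n")


def write_node_attributes(values, path, labels: list[str] | None = None, name: str = "theta") -> None:
    """Node-attribute TSV: label <tab> value, canonical label order."""
    values = np.asarray(values)
    if labels is None:
        width = len(str(max(len(values) - 1, 0)))
        labels = [f"n{i:0{width}d}" for i in range(len(values))]
    with open(path, "w") as fh:
        fh.write(f"# node\t{name}\n")
        for lab, val in sorted(zip(labels, values.tolist())):
            fh.write(f"{lab}\t{val}\n")


def read_node_attributes(path) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise EdgeListParseError(f"{path}:{lineno}: expected label<TAB>value")
            out[parts[0]] = float(parts[1])
    return out


def write_graphml(state: NetworkState, path, labels=None, theta=None) -> None:
    """Optional GraphML export; embeds theta as a node attribute when given."""
    g = state.to_networkx()
    if labels is not None:
        g = nx.relabel_nodes(g, dict(enumerate(labels)))
        nodes = labels
    else:
        nodes = range(state.N)
    if theta is not None:
        nx.set_node_attributes(
            g, {n: float(t) for n, t in zip(nodes, np.asarray(theta))}, "theta"
        )
    nx.write_graphml(g, Path(path))
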