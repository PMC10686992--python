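"""Readers and writers for edge lists, attribute tables, and mixing matrices.

Edge lists are two-column delimited text (tab by default); lines starting
with '#' are comments.  Node attributes are two-column delimited text
(node, category).  GraphML is read through networkx, taking group labels
from a named node attribute.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np

from .mixing import MixingMatrix

__all__ = [
    "read_edge_list",
    "read_attributes",
    "read_graphml",
    "mixing_to_json",
    "mixing_from_json",
    "write_mixing_tsv",
    "write_edge_list",
    "write_attributes",
]


def read_edge_list(path, delimiter: str = "\t") -> list[tuple[str, str]]:
    edges = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(delimiter)
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        edges.append((parts[0], parts[1]))
    return edges


def read_attributes(path, delimiter: str = "\t") -> dict[str, str]:
    labels: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(delimiter)
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns")
        labels[parts[0]] = parts[1]
    return labels


def read_graphml(path, attr: str) -> tuple[list, dict]:
    """Edge list and node->category map from a GraphML node attribute."""
    g = nx.read_graphml(path)
    labels = {}
    for node, data in g.nodes(data=True):
        if attr not in data:
            raise ValueError(f"node {node!r} lacks attribute {attr!r}")
        labels[node] = data[attr]
    return list(g.edges()), labels


def mixing_to_json(m: MixingMatrix) -> str:
    return json.dumps({
        "groups": list(m.groups) if m.groups else None,
        "e": m.e.tolist(),
        "a": m.a.tolist(),
        "b": m.b.tolist(),
        "adjusted": m.adjusted,
    }, indent=2)


def mixing_from_json(text: str) -> MixingMatrix:
    obj = json.loads(text)
    return MixingMatrix(
        e=np.array(obj["e"]), a=np.array(obj["a"]), b=np.array(obj["b"]),
        adjusted=obj.get("adjusted", False),
        groups=tuple(obj["groups"]) if obj.get("groups") else None)


def write_mixing_tsv(m: MixingMatrix, path) -> None:
    names = m.groups or tuple(range(m.n_groups))
    lines = ["\t".join(["group"] + [str(g) for g in names])]
    for g, row in zip(names, m.e):
        lines.append("\t".join([str(g)] + [f"{x:.10g}" for x in row]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_edge_list(edges, path, delimiter: str = "\t") -> None:
    Path(path).write_text(
        "".join(f"{u}{delimiter}{v}\n" for u, v in edges))


def write_attributes(labels, path, delimiter: str = "\t") -> None:
    Path(path).write_text(
        "".join(f"{node}{delimiter}{cat}\n" for node, cat in labels.items()))
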