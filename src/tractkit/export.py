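"""Connectome exporters: GraphML / GML / DOT graphs and CSV matrices."""

from __future__ import annotations

import json
import os

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import Connectome


class ExportFormatError(ValueError):
    """Unknown export format."""


def connectome_to_graph(c: Connectome) -> nx.Graph:
    """Undirected graph: nodes carry id/name/parent, edges every measure."""
    g = nx.Graph()
    for lab in c.labels:
        info = c.node_table[lab]
        g.add_node(
            int(lab),
            name=str(info.get("name", f"label_{lab}")),
            region=str(info.get("region", "")),
            surface=float(info.get("surface", 0.0)),
        )
    n = len(c.labels)
    for i in range(n):
        for j in range(i, n):
            attrs = {}
            for measure, mat in c.matrices.items():
                if mat[i, j]:
                    attrs[measure] = float(mat[i, j])
            if attrs.get("fibre_count"):
                # display convenience alongside the raw count
                attrs["log_fibre_count"] = float(np.log10(1.0 + attrs["fibre_count"]))
                g.add_edge(int(c.labels[i]), int(c.labels[j]), **attrs)
    return g


def _write_dot(g: nx.Graph, path: str) -> None:
    # minimal DOT writer (no pydot dependency); attributes as quoted strings
    lines = ["graph connectome {"]
    for n, d in sorted(g.nodes(data=True)):
        attrs = ", ".join(f'{k}="{v}"' for k, v in sorted(d.items()))
        lines.append(f"  {n} [{attrs}];")
    for a, b, d in sorted(g.edges(data=True)):
        attrs = ", ".join(f'{k}="{v}"' for k, v in sorted(d.items()))
        lines.append(f"  {a} -- {b} [{attrs}];")
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_graph(c: Connectome, fmt: str, path: str | os.PathLike) -> None:
    """Write the connectome graph as ``graphml``, ``gml`` or ``dot``."""
    g = connectome_to_graph(c)
    path = str(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gml":
        nx.write_gml(g, path)
    elif fmt == "dot":
        _write_dot(g, path)
    else:
        raise ExportFormatError(f"unknown graph format {fmt!r}")


def export_matrices(c: Connectome, out_dir: str | os.PathLike, prefix: str = "connectome") -> list:
    """One CSV per measure (node labels as header/index); returns the paths."""
    os.makedirs(str(out_dir), exist_ok=True)
    paths = []
    for measure in sorted(c.matrices):
        df = pd.DataFrame(c.matrices[measure], index=c.labels, columns=c.labels)
        p = os.path.join(str(out_dir), f"{prefix}_scale{c.scale}_{measure}.csv")
        df.to_csv(p, float_format="%.10g")
        paths.append(p)
    return paths


def export_node_table(c: Connectome, path: str | os.PathLike) -> None:
    table = {
        str(lab): {k: (float(v) if isinstance(v, (int, float, np.floating)) else str(v))
                   for k, v in c.node_table[lab].items()}
        for lab in c.labels
    }
    with open(str(path), "w") as fh:
        json.dump(table, fh, indent=1, sort_keys=True)
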