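"""Serialise enrichment results: ranked TSV table and network formats.

Supported network formats: GraphML, SIF (lossy: edges only) and a
node-link JSON dialect mirroring the GraphML attributes.  Output ordering
is deterministic (sorted nodes and edges) so identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
import math
import os
from typing import IO, Iterable

import networkx as nx

from .pruning import ResultGraph
from .stats import EnrichmentRow

FORMATS = ("tsv", "graphml", "sif", "node_link_json")

TABLE_COLUMNS = (
    "class_id",
    "name",
    "k",
    "n",
    "K",
    "N",
    "p_raw",
    "p_adj",
    "sample_pct",
    "fold",
)


class ExportError(ValueError):
    pass


def _fmt(value: float | None) -> str:
    if value is None:
        return ""
    return f"{value:.6g}"


def write_table(rows: Iterable[EnrichmentRow], dest: str | os.PathLike | IO[str]) -> None:
    """Write the ranked result table as TSV (header always present)."""
    own = not hasattr(dest, "write")
    handle = open(dest, "w", encoding="utf-8") if own else dest
    try:
        handle.write("\t".join(TABLE_COLUMNS) + "\n")
        for r in rows:
            handle.write(
                "\t".join(
                    (
                        r.class_id,
                        r.name,
                        str(r.k),
                        str(r.n),
                        str(r.K),
                        str(r.N),
                        _fmt(r.p_raw),
                        _fmt(r.p_adj),
                        _fmt(r.sample_pct),
                        _fmt(r.fold),
                    )
                )
                + "\n"
            )
    finally:
        if own:
            handle.close()


def _significance(p_adj: float) -> float:
    # monotone display score standing in for the colour/transparency ramp
    return -math.log10(max(p_adj, 1e-300))


def _export_nx(rg: ResultGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    for node in sorted(rg.graph.nodes):
        attrs = {
            "name": rg.graph.nodes[node].get("name", ""),
            "is_molecule": bool(rg.graph.nodes[node].get("is_molecule", False)),
        }
        row = rg.node_stats.get(node)
        if row is not None:
            attrs.update(
                p_raw=float(row.p_raw),
                p_adj=float(row.p_adj),
                sample_pct=float(row.sample_pct),
                significance=_significance(row.p_adj),
            )
            if row.fold is not None:
                attrs["fold"] = float(row.fold)
        g.add_node(node, **attrs)
    for child, parent in sorted(rg.graph.edges):
        g.add_edge(
            child,
            parent,
            relation=rg.graph[child][parent]["relation"],
            collapsed_count=len(rg.collapsed_paths.get((child, parent), [])),
        )
    return g


def write_graph(
    rg: ResultGraph,
    rows: Iterable[EnrichmentRow] | None,
    fmt: str,
    dest: str | os.PathLike,
) -> None:
    """Write the result graph in ``fmt`` (graphml, sif or node_link_json)."""
    if rows is not None:
        merged = dict(rg.node_stats)
        merged.update({r.class_id: r for r in rows if rg.graph.has_node(r.class_id)})
        rg = ResultGraph(rg.graph, merged, rg.collapsed_paths)
    if fmt == "graphml":
        nx.write_graphml(_export_nx(rg), dest, infer_numeric_types=False)
    elif fmt == "sif":
        with open(dest, "w", encoding="utf-8") as fh:
            for child, parent in sorted(rg.graph.edges):
                rel = rg.graph[child][parent]["relation"]
                fh.write(f"{child}\t{rel}\t{parent}\n")
    elif fmt == "node_link_json":
        g = _export_nx(rg)
        doc = {
            "directed": True,
            "nodes": [{"id": n, **g.nodes[n]} for n in g.nodes],
            "links": [{"source": c, "target": p, **g[c][p]} for c, p in g.edges],
        }
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ExportError(f"unknown graph format {fmt!r}")


def read_node_link_json(path: str | os.PathLike) -> nx.DiGraph:
    """Reload a node-link JSON export (round-trip helper)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    g = nx.DiGraph()
    for node in doc["nodes"]:
        attrs = dict(node)
        g.add_node(attrs.pop("id"), **attrs)
    for link in doc["links"]:
        attrs = dict(link)
        g.add_edge(attrs.pop("source"), attrs.pop("target"), **attrs)
    return g
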