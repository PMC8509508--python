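"""The weighted, undirected drug co-reporting network.

Nodes are normalized ingredient names with attributes ``count`` (reports
containing the drug), ``prevalence`` and ``atc1`` (anatomical main group,
the conventional node color).  An edge joins two drugs reported together in
at least one report; its ``weight`` is the number of such reports — exactly
the pair count from :mod:`agepnet.cooccurrence`.  There are no self-loops
and edges are stored once (undirected).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional

import networkx as nx

from .cooccurrence import count_ksets, marginal_counts, oe_ratio
from .types import ReportSet

_FORMATS = ("graphml", "gexf", "csv")


def build_graph(report_set: ReportSet, attach_oe: bool = False) -> nx.Graph:
    """Build the co-reporting network from a retained cohort.

    Node ``count`` equals the marginal report count, edge ``weight`` the
    pair count; ``attach_oe`` additionally stores each edge's pair O/E
    ratio (exploratory attribute — weights stay raw counts).
    """
    if report_set.n_reports == 0:
        raise ValueError("cannot build a network from an empty report set")
    n_reports = report_set.n_reports
    marg = marginal_counts(report_set)
    pairs = count_ksets(report_set, 2)

    graph = nx.Graph()
    for drug in sorted(marg):
        graph.add_node(
            drug,
            count=int(marg[drug]),
            prevalence=marg[drug] / n_reports,
            atc1=report_set.atc1_of(drug),
        )
    for pair in sorted(pairs, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        graph.add_edge(a, b, weight=int(pairs[pair]))
    if attach_oe:
        stats = oe_ratio(pairs, marg, n_reports)
        for drugs, oe in zip(stats["drugs"], stats["oe"]):
            graph.edges[drugs]["oe"] = float(oe)
    return graph


def filter_graph(
    graph: nx.Graph, min_edge_weight: int = 1, min_node_count: int = 0
) -> nx.Graph:
    """Copy of ``graph`` without light edges, small nodes, then isolates.

    Edges below ``min_edge_weight`` are removed first, then nodes whose
    ``count`` attribute falls below ``min_node_count``, then nodes left
    isolated.  The original graph is untouched.
    """
    if min_edge_weight < 0 or min_node_count < 0:
        raise ValueError("thresholds must be >= 0")
    out = graph.copy()
    drop_edges = [
        (u, v) for u, v, w in out.edges(data="weight")
        if w < min_edge_weight
    ]
    out.remove_edges_from(drop_edges)
    drop_nodes = [
        n for n, c in out.nodes(data="count", default=0)
        if c < min_node_count
    ]
    out.remove_nodes_from(drop_nodes)
    out.remove_nodes_from(list(nx.isolates(out)))
    return out


def _infer_format(path, fmt: Optional[str]) -> str:
    if fmt:
        fmt = fmt.lower()
    else:
        fmt = Path(path).suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; use one of {_FORMATS}")
    return fmt


def export_graph(graph: nx.Graph, path, fmt: Optional[str] = None) -> None:
    """Write GraphML, GEXF 1.2 or an edge-list CSV (source,target,weight[,oe]).

    GraphML/GEXF round-trip all node and edge attributes (ready for Gephi);
    the CSV carries edges and weights only.
    """
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "gexf":
        nx.write_gexf(graph, path, version="1.2draft")
    else:
        has_oe = any("oe" in d for _, _, d in graph.edges(data=True))
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            header = ["source", "target", "weight"] + (["oe"] if has_oe else [])
            writer.writerow(header)
            for u, v, data in sorted(graph.edges(data=True)):
                row = [u, v, data["weight"]]
                if has_oe:
                    row.append(data.get("oe", ""))
                writer.writerow(row)


def read_graph(path, fmt: Optional[str] = None) -> nx.Graph:
    """Re-import a graph written by :func:`export_graph`."""
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        return nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
    if fmt == "gexf":
        graph = nx.read_gexf(path)
        graph = nx.relabel_nodes(graph, {n: str(n) for n in graph.nodes})
        for n in graph.nodes:
            graph.nodes[n].pop("label", None)
        return graph
    out = nx.Graph()
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            attrs = {"weight": int(row["weight"])}
            if row.get("oe") not in (None, ""):
                attrs["oe"] = float(row["oe"])
            out.add_edge(row["source"], row["target"], **attrs)
    return out


def total_edge_weight(graph: nx.Graph) -> int:
    return int(sum(w for _, _, w in graph.edges(data="weight")))
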