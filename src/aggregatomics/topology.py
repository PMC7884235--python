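"""Topology statistics and export for inferred co-occurrence networks.

Signs are ignored for topology: a negative (exclusion) association still
makes its endpoints part of the same network structure.  Betweenness is
reported unnormalized (raw Brandes pair counts) so values are directly
comparable across networks of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Union

import networkx as nx
import pandas as pd

from .network import NetworkResult

__all__ = [
    "TopologySummary",
    "as_graph",
    "connected_components",
    "degree",
    "betweenness",
    "topology_summary",
    "export_network",
    "read_graphml",
]

GraphLike = Union[nx.Graph, NetworkResult]


def as_graph(network: GraphLike, positive_only: bool = False) -> nx.Graph:
    """Coerce a network result to an undirected graph.

    ``positive_only`` drops exclusion (sign = -1) edges first.
    """
    G = network.to_networkx() if isinstance(network, NetworkResult) else network.copy()
    if positive_only:
        drop = [(u, v) for u, v, d in G.edges(data=True) if d.get("sign", 1) < 0]
        G.remove_edges_from(drop)
    return G


def connected_components(network: GraphLike) -> List[set]:
    """Node sets of the connected components, largest first."""
    G = as_graph(network)
    return sorted(nx.connected_components(G), key=len, reverse=True)


def degree(network: GraphLike) -> Dict[str, int]:
    """Incident-edge count per node, signs ignored."""
    return dict(as_graph(network).degree())


def betweenness(network: GraphLike) -> Dict[str, float]:
    """Unnormalized shortest-path betweenness centrality (Brandes)."""
    return nx.betweenness_centrality(as_graph(network), normalized=False)


@dataclass
class TopologySummary:
    """Headline topology numbers of one network."""

    n_nodes: int
    n_edges: int
    component_sizes: List[int]
    degrees: pd.Series
    betweenness: pd.Series
    top_degree_node: str
    top_betweenness_nodes: List[str]


def topology_summary(network: GraphLike, n_top: int = 3) -> TopologySummary:
    """Degree, betweenness and component structure in one report.

    ``top_betweenness_nodes`` ranks candidates for a bridging "keystone"
    role; no numeric cutoff is imposed.
    """
    G = as_graph(network)
    deg = pd.Series(dict(G.degree()), dtype=int).sort_values(ascending=False)
    btw = pd.Series(betweenness(G), dtype=float).sort_values(ascending=False)
    comps = sorted((len(c) for c in nx.connected_components(G)), reverse=True)
    return TopologySummary(
        n_nodes=G.number_of_nodes(),
        n_edges=G.number_of_edges(),
        component_sizes=comps,
        degrees=deg,
        betweenness=btw,
        top_degree_node=deg.index[0] if len(deg) else "",
        top_betweenness_nodes=list(btw.index[:n_top]),
    )


def export_network(network: GraphLike, path, format: str = "graphml") -> None:
    """Write a network as GraphML or a tab-delimited edge list.

    GraphML carries node attributes (abundance, degree, betweenness) and
    edge attributes (sign, support, p, q) and round-trips through
    :func:`read_graphml`.
    """
    G = as_graph(network)
    if format == "graphml":
        deg = dict(G.degree())
        btw = betweenness(G)
        for node in G.nodes:
            G.nodes[node]["degree"] = int(deg[node])
            G.nodes[node]["betweenness"] = float(btw[node])
        nx.write_graphml(G, path)
    elif format == "edgelist":
        if isinstance(network, NetworkResult):
            network.edge_table().to_csv(path, sep="\t", index=False)
        else:
            rows = [
                {"sv_a": u, "sv_b": v, **{k: d[k] for k in sorted(d)}}
                for u, v, d in G.edges(data=True)
            ]
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
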