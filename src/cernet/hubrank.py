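"""Hub-node ranking by Degree and Maximal Clique Centrality (MCC).

MCC(v) = sum over maximal cliques C containing v of (|C|-1)!. An isolated
node belongs to the maximal clique {v}, so MCC >= 1 everywhere; on a
triangle-free graph every maximal clique at a non-isolated node is an edge,
so MCC reduces to degree. Ranked lists break score ties by node id
(ascending) so a top-k extraction is deterministic.
"""

from __future__ import annotations

from math import factorial
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = ["as_simple_graph", "enumerate_maximal_cliques", "mcc_scores",
           "degree_scores", "top_k", "hub_table"]

DEFAULT_NODE_CEILING = 5000


def as_simple_graph(edges: Iterable[tuple[str, str]] | nx.Graph) -> nx.Graph:
    """Collapse an edge list (or any graph) to a simple undirected graph,
    dropping self-loops and duplicate edges."""
    g = nx.Graph()
    if isinstance(edges, nx.Graph):
        g.add_nodes_from(edges.nodes())
        g.add_edges_from((u, v) for u, v in edges.edges() if u != v)
    else:
        for u, v in edges:
            if u != v:
                g.add_edge(u, v)
            else:
                g.add_node(u)
    return g


def _check_graph(graph: nx.Graph, node_ceiling: int) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise ValueError("expected a simple undirected graph; "
                         "use as_simple_graph() first")
    if any(u == v for u, v in graph.edges()):
        raise ValueError("graph contains self-loops; use as_simple_graph()")
    if graph.number_of_nodes() > node_ceiling:
        raise ValueError(
            f"graph has {graph.number_of_nodes()} nodes, above the clique "
            f"enumeration ceiling of {node_ceiling}; raise node_ceiling "
            "explicitly if this is intended")


def enumerate_maximal_cliques(graph: nx.Graph,
                              node_ceiling: int = DEFAULT_NODE_CEILING
                              ) -> list[frozenset]:
    """All inclusion-maximal cliques, each once (order unspecified)."""
    _check_graph(graph, node_ceiling)
    return [frozenset(c) for c in nx.find_cliques(graph)]


def mcc_scores(graph: nx.Graph,
               node_ceiling: int = DEFAULT_NODE_CEILING) -> dict[str, int]:
    """Maximal Clique Centrality for every node."""
    scores = {v: 0 for v in graph.nodes()}
    for clique in enumerate_maximal_cliques(graph, node_ceiling):
        w = factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def degree_scores(graph: nx.Graph) -> dict[str, int]:
    return {v: d for v, d in graph.degree()}


def top_k(scores: Mapping[str, float], k: int) -> list[str]:
    """Top-k node ids by score descending, ties by id ascending; returns
    min(k, n) nodes."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(scores, key=lambda v: (-scores[v], str(v)))
    return ranked[:k]


def hub_table(graph: nx.Graph,
              node_ceiling: int = DEFAULT_NODE_CEILING) -> pd.DataFrame:
    """Per-node degree and MCC with dense ranks under each method."""
    deg = degree_scores(graph)
    mcc = mcc_scores(graph, node_ceiling)
    order_deg = top_k(deg, max(len(deg), 1)) if deg else []
    order_mcc = top_k(mcc, max(len(mcc), 1)) if mcc else []
    rank_deg = {v: i + 1 for i, v in enumerate(order_deg)}
    rank_mcc = {v: i + 1 for i, v in enumerate(order_mcc)}
    nodes = sorted(graph.nodes(), key=str)
    return pd.DataFrame({
        "node_id": nodes,
        "degree": [deg[v] for v in nodes],
        "mcc": [mcc[v] for v in nodes],
        "rank_degree": [rank_deg[v] for v in nodes],
        "rank_mcc": [rank_mcc[v] for v in nodes],
    })


def read_edge_tsv(path: str | Path) -> nx.Graph:
    """Two-column (or more; extra columns ignored) edge list TSV."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return as_simple_graph(df[cols].astype(str).itertuples(index=False, name=None))
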