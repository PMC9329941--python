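"""Consensus protein-protein interaction networks over candidate genes.

Interactions from several source databases are merged into one
undirected simple graph; an edge is kept only when at least
``min_db_support`` distinct databases report it (a database contributes
at most one unit of support per gene pair, however many rows it
supplies, and direction is ignored).  Self-interactions are removed.
Candidate subnetworks are induced subgraphs with isolated nodes dropped;
disease-gene-augmented subnetworks additionally exclude edges between
two non-candidate genes and flag high-degree hubs for display masking
(the analysis graph itself keeps them).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = [
    "build_consensus_network",
    "candidate_subgraph",
    "ndd_augmented_subgraph",
    "assert_simple_undirected",
]


def build_consensus_network(
    edge_table: pd.DataFrame,
    min_db_support: int = 2,
) -> nx.Graph:
    """Build the consensus graph from a (gene_a, gene_b, source_db) table.

    Gene pairs are unordered; duplicate rows within one database count
    once.  Edges carry ``source_dbs`` (sorted tuple) and ``support``
    attributes.
    """
    support: dict[tuple[str, str], set[str]] = {}
    for row in edge_table.itertuples(index=False):
        a, b = row.gene_a, row.gene_b
        if a == b:
            continue  # self-interactions removed
        pair = (a, b) if a <= b else (b, a)
        support.setdefault(pair, set()).add(row.source_db)
    g = nx.Graph()
    for (a, b), dbs in support.items():
        if len(dbs) >= min_db_support:
            g.add_edge(a, b, source_dbs=tuple(sorted(dbs)), support=len(dbs))
    return g


def candidate_subgraph(
    graph: nx.Graph,
    candidate_genes: set[str],
    drop_isolated: bool = True,
) -> nx.Graph:
    """Induced subgraph on the candidate genes, optionally dropping
    nodes left without any within-candidate interaction."""
    sub = graph.subgraph(set(candidate_genes) & set(graph.nodes)).copy()
    if drop_isolated:
        sub.remove_nodes_from(list(nx.isolates(sub)))
    return sub


def ndd_augmented_subgraph(
    graph: nx.Graph,
    candidates: set[str],
    ndd_genes: set[str],
    max_degree_shown: int = 13,
    drop_isolated: bool = True,
) -> tuple[nx.Graph, set[str]]:
    """Candidate network augmented with known disease genes.

    Induces the subgraph on candidates plus disease genes, removes every
    edge joining two non-candidate genes (the augmentation only shows how
    disease genes connect to candidates), and drops isolated nodes.
    Returns the graph and a display mask: nodes whose degree in the
    returned graph exceeds ``max_degree_shown`` (to be hidden when drawn;
    the graph itself is unchanged).
    """
    nodes = (set(candidates) | set(ndd_genes)) & set(graph.nodes)
    sub = graph.subgraph(nodes).copy()
    sub.remove_edges_from(
        [(a, b) for a, b in sub.edges if a not in candidates and b not in candidates]
    )
    if drop_isolated:
        sub.remove_nodes_from(list(nx.isolates(sub)))
    hidden = {n for n in sub.nodes if sub.degree(n) > max_degree_shown}
    return sub, hidden


def assert_simple_undirected(graph: nx.Graph) -> None:
    """Sanity check used by callers and tests: no self-loops, undirected,
    not a multigraph."""
    if graph.is_directed() or graph.is_multigraph():
        raise AssertionError("graph must be a simple undirected nx.Graph")
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise AssertionError(f"graph contains self-loops: {loops[:3]}")
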