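"""Degree and betweenness-centrality reports on causal networks.

Degree counts incident edges (in + out); antiparallel edges between the
same pair count separately and a self-loop counts once.  Betweenness is
the standard shortest-path centrality, directed by default (regulatory
edges have direction) and normalised by (n-1)(n-2); self-loops are
excluded.  Ordered pairs with no connecting path contribute 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .iodb import DEFAULT_SIGN_VOCAB, Interaction
from .propagate import CausalNetwork


def _edge_list(network) -> list[tuple[str, str]]:
    if isinstance(network, CausalNetwork):
        return [(ia.source, ia.target) for ia in network.edges]
    if isinstance(network, nx.Graph):
        return list(network.edges())
    return [(ia.source, ia.target) for ia in network]


def _node_list(network) -> list[str]:
    if isinstance(network, CausalNetwork):
        return sorted(network.nodes)
    if isinstance(network, nx.Graph):
        return list(network.nodes())
    nodes = {ia.source for ia in network} | {ia.target for ia in network}
    return sorted(nodes)


def degree(network, node: str) -> int:
    """Number of edges incident on ``node`` (in + out, self-loops once)."""
    nodes = _node_list(network)
    if node not in nodes:
        raise KeyError(f"unknown node {node!r}")
    n = 0
    for u, v in _edge_list(network):
        if u == v:
            n += u == node
        else:
            n += (u == node) + (v == node)
    return n


def betweenness(network, directed: bool = True) -> dict[str, float]:
    """Normalised shortest-path betweenness centrality per node."""
    cls = nx.DiGraph if directed else nx.Graph
    g = cls()
    g.add_nodes_from(_node_list(network))
    g.add_edges_from((u, v) for u, v in _edge_list(network) if u != v)
    return nx.betweenness_centrality(g, normalized=True)


def centrality_report(network, directed: bool = True) -> pd.DataFrame:
    """Per-node degree and betweenness, sorted by degree descending."""
    btw = betweenness(network, directed=directed)
    rows = [
        {"gene": n, "degree": degree(network, n), "betweenness": btw[n]}
        for n in _node_list(network)
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["degree", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )


def read_sif(path: str | Path) -> list[Interaction]:
    """Read a three-column SIF file back into interactions."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            source, relation, target = line.rstrip("\n").split("\t")[:3]
            sign = DEFAULT_SIGN_VOCAB.get(relation.lower(), 0)
            out.append(Interaction(source, sign, target))
    return out
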