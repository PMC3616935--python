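"""Topological analysis of the pathway interaction graph.

Edges are unweighted and undirected (interaction presence, not strength).
Closeness uses the within-component convention, closeness(v) =
(n_c - 1) / sum of shortest-path distances inside v's component;
betweenness is the unnormalised count over unordered pairs of the fraction
of shortest paths passing through a node (endpoints excluded), with the
normalised variant emitted alongside.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CENTRALITY_COLUMNS = [
    "node", "degree", "closeness", "betweenness", "betweenness_normalized",
    "component",
]


def centralities(G: nx.Graph) -> pd.DataFrame:
    """Degree, closeness and betweenness for every node.

    Disconnected graphs are handled per component (closeness is undefined
    across components) with a prominent warning.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    components = list(nx.connected_components(G))
    if len(components) > 1:
        logger.warning(
            "network has %d connected components; closeness computed "
            "within components", len(components),
        )
    comp_of = {}
    for cid, comp in enumerate(components):
        for v in comp:
            comp_of[v] = cid
    closeness = nx.closeness_centrality(G, wf_improved=False)
    betweenness = nx.betweenness_centrality(G, normalized=False)
    betweenness_norm = nx.betweenness_centrality(G, normalized=True)
    rows = [
        dict(
            node=v,
            degree=G.degree(v),
            closeness=closeness[v],
            betweenness=betweenness[v],
            betweenness_normalized=betweenness_norm[v],
            component=comp_of[v],
        )
        for v in G.nodes
    ]
    return pd.DataFrame(rows, columns=CENTRALITY_COLUMNS)


def neighbor_mean(G: nx.Graph, values: dict) -> dict:
    """Mean of defined neighbor values per node; NaN when none are defined."""
    out = {}
    for v in G.nodes:
        vals = [
            values[u]
            for u in G.neighbors(v)
            if u in values and np.isfinite(values[u])
        ]
        out[v] = float(np.mean(vals)) if vals else float("nan")
    return out


def write_centralities(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
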