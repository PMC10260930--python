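"""Node centrality measures of the residue interaction network.

Seven measures are computed per residue: degree, betweenness, closeness,
k-core number, Burt's constraint, HITS authority and PageRank.  Conventions
(fixed; downstream steps — ranks, bins over observed ranges, Pareto
dominance — are invariant to them):

* betweenness is **unnormalized** (raw shortest-path pair counts), so that a
  log10-betweenness axis on a ~1400-node protein graph spans roughly 0–5;
* closeness is the Wasserman–Faust component-scaled form,
  ``(n_c - 1) / sum(d) * (n_c - 1) / (n - 1)``, which stays in (0, 1] on
  connected graphs and degrades gracefully on disconnected ones;
* authority: on an undirected graph the HITS authority vector coincides
  with eigenvector centrality; computed by power iteration (tol 1e-12) and
  max-normalized so the most authoritative node scores 1;
* PageRank uses damping 0.85 and sums to 1 over nodes.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = ["CENTRALITY_MEASURES", "compute_centralities", "spearman_matrix", "authority_scores"]

CENTRALITY_MEASURES = (
    "degree",
    "betweenness",
    "closeness",
    "kcore",
    "burts_constraint",
    "authority",
    "pagerank",
)

PAGERANK_DAMPING = 0.85


def authority_scores(graph: nx.Graph, tol: float = 1e-12, max_iter: int = 10_000) -> dict:
    """HITS authority by power iteration on the adjacency matrix, max-normalized."""
    nodes = list(graph.nodes())
    n = len(nodes)
    if n == 0:
        return {}
    if graph.number_of_edges() == 0:
        return {node: 0.0 for node in nodes}
    index = {node: i for i, node in enumerate(nodes)}
    a = np.zeros((n, n))
    for u, v in graph.edges():
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        y = a @ x
        norm = np.abs(y).max()
        if norm == 0:
            return {node: 0.0 for node in nodes}
        y /= norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    x /= x.max()
    return {node: float(score) for node, score in zip(nodes, x)}


def compute_centralities(graph: nx.Graph) -> pd.DataFrame:
    """One row per node with the seven centrality measures; deterministic.

    Burt's constraint is undefined (NaN) for isolated nodes.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if any(u == v for u, v in graph.edges()):
        raise ValueError("graph must be simplified (self-loops present)")

    nodes = list(graph.nodes())
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    kcore = nx.core_number(graph)
    constraint = nx.constraint(graph)
    authority = authority_scores(graph)
    if graph.number_of_edges() > 0:
        pagerank = nx.pagerank(graph, alpha=PAGERANK_DAMPING, tol=1e-12, max_iter=500)
    else:
        pagerank = {node: 1.0 / len(nodes) for node in nodes}

    table = pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "kcore": [kcore[n] for n in nodes],
            "burts_constraint": [constraint[n] for n in nodes],
            "authority": [authority[n] for n in nodes],
            "pagerank": [pagerank[n] for n in nodes],
        },
        index=pd.Index(nodes, name="residue", tupleize_cols=False),
    )
    return table


def spearman_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank-correlation matrix of the centrality measures.

    A constant column has no rank ordering: its correlations are reported as
    NaN (missing), never coerced to 0.
    """
    measures = [m for m in CENTRALITY_MEASURES if m in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a rank correlation")
    k = len(measures)
    out = np.full((k, k), np.nan)
    values = table[measures].to_numpy(dtype=float)
    constant = [np.unique(values[np.isfinite(values[:, i]), i]).size < 2 for i in range(k)]
    for i in range(k):
        if not constant[i]:
            out[i, i] = 1.0
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                continue
            xi, xj = values[:, i], values[:, j]
            mask = np.isfinite(xi) & np.isfinite(xj)
            out[i, j] = out[j, i] = spearmanr(xi[mask], xj[mask]).statistic
    return pd.DataFrame(out, index=measures, columns=measures)
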