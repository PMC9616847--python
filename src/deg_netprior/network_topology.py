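"""Round-2 screening: six node centralities combined into a topological score.

The six metrics (degree, betweenness, closeness, radiality, stress,
eigenvector centrality) are computed on the unweighted graph, per connected
component where path-based. Because their scales are incomparable (integer
stress vs. real closeness), each metric is converted to a percentile rank
across nodes and the composite score is the mean of the six percentiles;
nodes at or above the selection mark (default 50) survive.

Conventions: betweenness and stress count each unordered source-target pair
once and are not normalized; closeness(v) = (n_c - 1) / sum of distances
within v's component of size n_c; radiality(v) averages (diam_c + 1 - d(v,u))
over the other component members; eigenvector centrality is the principal
eigenvector of the component adjacency matrix at unit Euclidean norm. In a
singleton component all path-based metrics are 0 and the eigenvector entry
is 1.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from deg_netprior.go_ranking import percentile_rank

METRICS = (
    "degree",
    "betweenness",
    "closeness",
    "radiality",
    "stress",
    "eigenvector",
)


def induced_subnetwork(network: nx.Graph, genes: set[str]) -> nx.Graph:
    """Subgraph induced on ``genes`` ∩ network nodes (copy, not a view)."""
    return network.subgraph(set(genes) & set(network.nodes)).copy()


def _bfs_counts(graph: nx.Graph, source):
    """Distances and shortest-path counts (sigma) from one source."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = [source]
    while queue:
        next_queue = []
        for u in queue:
            for w in graph[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    next_queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        queue = next_queue
    return dist, sigma


def _stress(graph: nx.Graph) -> dict:
    """stress(v) = number of shortest paths with v as an interior node."""
    nodes = list(graph.nodes)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_counts(graph, s)
    stress = dict.fromkeys(nodes, 0)
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in dist[s]:
                if v == s or v == t:
                    continue
                if dist[s][v] + dist[v].get(t, np.inf) == d_st:
                    stress[v] += sigma[s][v] * sigma[v][t]
    return stress


def _radiality(graph: nx.Graph) -> dict:
    radiality = {}
    for component in nx.connected_components(graph):
        members = sorted(component)
        sub = graph.subgraph(members)
        n_c = len(members)
        if n_c == 1:
            radiality[members[0]] = 0.0
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(d for row in lengths.values() for d in row.values())
        for v in members:
            total = sum(diam + 1 - d for u, d in lengths[v].items() if u != v)
            radiality[v] = total / (n_c - 1)
    return radiality


def _eigenvector(graph: nx.Graph) -> dict:
    eigenvector = {}
    for component in nx.connected_components(graph):
        members = sorted(component)
        if len(members) == 1:
            eigenvector[members[0]] = 1.0
            continue
        adjacency = nx.to_numpy_array(graph.subgraph(members), nodelist=members)
        values, vectors = np.linalg.eigh(adjacency)
        principal = vectors[:, np.argmax(values)]
        # Perron vector of a connected graph is strictly one-signed.
        if principal.sum() < 0:
            principal = -principal
        principal = principal / np.linalg.norm(principal)
        for node, value in zip(members, principal):
            eigenvector[node] = float(value)
    return eigenvector


def compute_centralities(network: nx.Graph) -> pd.DataFrame:
    """All six centralities per node, indexed by node id."""
    nodes = sorted(network.nodes)
    if not nodes:
        return pd.DataFrame(columns=list(METRICS))
    betweenness = nx.betweenness_centrality(network, normalized=False)
    closeness = nx.closeness_centrality(network, wf_improved=False)
    frame = pd.DataFrame(
        {
            "degree": {v: network.degree(v) for v in nodes},
            "betweenness": betweenness,
            "closeness": closeness,
            "radiality": _radiality(network),
            "stress": _stress(network),
            "eigenvector": _eigenvector(network),
        }
    ).loc[nodes]
    frame.index.name = "gene_id"
    return frame


def composite_topology_score(centralities: pd.DataFrame) -> pd.DataFrame:
    """Mean of the six per-metric percentile ranks, in [0, 100]."""
    if centralities.empty:
        raise ValueError("need at least one node to score")
    out = centralities.copy()
    percentile_cols = []
    for metric in METRICS:
        # round away float noise so symmetric nodes tie exactly before ranking
        rounded = centralities[metric].round(9)
        ranks = percentile_rank(dict(rounded))
        col = f"percentile_{metric}"
        out[col] = pd.Series(ranks)
        percentile_cols.append(col)
    out["composite_score"] = out[percentile_cols].mean(axis=1)
    return out


def select_round2(
    scores: pd.DataFrame, mark: float = 50.0, below: bool = False
) -> set[str]:
    """Nodes whose composite score crosses the mark (>= by default).

    ``below=True`` selects composite <= mark instead, for the alternative
    reading of the screening direction.
    """
    if scores.empty:
        return set()
    if below:
        keep = scores["composite_score"] <= mark
    else:
        keep = scores["composite_score"] >= mark
    return set(scores.index[keep])


def network_summary(network: nx.Graph) -> dict:
    """Descriptive statistics (not used for selection)."""
    n = network.number_of_nodes()
    summary = {
        "nodes": n,
        "edges": network.number_of_edges(),
        "components": nx.number_connected_components(network) if n else 0,
        "clustering_coefficient": nx.average_clustering(network) if n else 0.0,
    }
    return summary
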