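"""MCODE-style detection of densely interconnected sub-networks.

Vertices are weighted by local core density: the weight of v is k x
density(C), where C is the highest k-core of the subgraph induced by v's
closed neighborhood. Complexes grow greedily from the highest-weight
unassigned seed, admitting unassigned neighbors whose weight exceeds
seed_weight x (1 - node_score_cutoff). Complexes that do not contain a
kappa-core (default 2) are discarded. Optional post-processing: haircut
removes degree-1 members; fluff attaches boundary neighbors whose
closed-neighborhood density exceeds the fluff density cutoff (default 0.1,
the density parameter quoted alongside the node score cutoff of 0.2).

A cluster's density is 2E/(n(n-1)) and its score density x n, both computed
over the cohesive core members; fluffed nodes are peripheral attachments,
reported separately and allowed to appear in more than one cluster. Edge
scores are ignored (binary adjacency) and all tie-breaks are lexicographic
on node id, so output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx


@dataclass(frozen=True)
class MCODEParams:
    node_score_cutoff: float = 0.2
    kcore: int = 2
    fluff: bool = True
    fluff_density: float = 0.1
    haircut: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if not 0.0 <= self.fluff_density <= 1.0:
            raise ValueError("fluff_density must be in [0, 1]")
        if self.kcore < 2:
            raise ValueError("kcore must be >= 2")


@dataclass(frozen=True)
class Cluster:
    """A detected complex: cohesive members plus optional fluffed periphery."""

    members: tuple[str, ...]
    fluffed: tuple[str, ...]
    n: int
    e: int
    density: float
    score: float
    seed: str

    def all_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.members) | set(self.fluffed)))


def graph_density(n: int, e: int) -> float:
    if n < 2:
        return 0.0
    return 2.0 * e / (n * (n - 1))


def cluster_score(n: int, e: int) -> tuple[float, float]:
    """(density, score) for a simple cluster with n nodes and e edges.

    score = density x n; e.g. 16 nodes with 66 edges score 8.8.
    """
    if n < 2:
        raise ValueError("a scorable cluster needs n >= 2 nodes")
    if e < 0 or e > n * (n - 1) // 2:
        raise ValueError("e exceeds the simple-graph maximum n(n-1)/2")
    density = graph_density(n, e)
    return density, density * n


def core_number(network: nx.Graph) -> dict[str, int]:
    """Largest k such that each node belongs to the k-core (0 for isolated)."""
    return nx.core_number(network)


def _closed_neighborhood(network: nx.Graph, node) -> nx.Graph:
    return network.subgraph(set(network[node]) | {node})


def vertex_weight(network: nx.Graph, node) -> float:
    """k x density of the highest k-core of the node's closed neighborhood."""
    neighborhood = _closed_neighborhood(network, node)
    if neighborhood.number_of_edges() == 0:
        return 0.0
    cores = nx.core_number(neighborhood)
    k = max(cores.values())
    top_core = [v for v, c in cores.items() if c >= k]
    sub = neighborhood.subgraph(top_core)
    return k * graph_density(sub.number_of_nodes(), sub.number_of_edges())


def _neighborhood_density(network: nx.Graph, node) -> float:
    sub = _closed_neighborhood(network, node)
    return graph_density(sub.number_of_nodes(), sub.number_of_edges())


def find_complexes(
    network: nx.Graph, params: MCODEParams | None = None
) -> list[Cluster]:
    """Detect complexes, highest-scoring first."""
    params = params or MCODEParams()
    if network.number_of_nodes() == 0:
        return []
    weights = {v: vertex_weight(network, v) for v in network.nodes}
    seed_order = sorted(network.nodes, key=lambda v: (-weights[v], str(v)))
    assigned: set = set()
    clusters: list[Cluster] = []
    for seed in seed_order:
        if seed in assigned:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        while frontier:
            next_frontier = []
            for u in sorted(frontier, key=str):
                for w in sorted(network[u], key=str):
                    if w in members or w in assigned:
                        continue
                    if weights[w] > threshold:
                        members.add(w)
                        next_frontier.append(w)
            frontier = next_frontier

        sub = network.subgraph(members)
        if not sub.number_of_edges() or max(nx.core_number(sub).values()) < params.kcore:
            continue  # no kappa-core: not a complex; nodes stay available
        if params.haircut:
            members = {v for v in members if sub.degree(v) > 1}
            sub = network.subgraph(members)
        assigned |= members

        fluffed: set = set()
        if params.fluff:
            boundary = {
                w for v in members for w in network[v] if w not in members
            }
            fluffed = {
                w
                for w in boundary
                if _neighborhood_density(network, w) > params.fluff_density
            }

        n, e = sub.number_of_nodes(), sub.number_of_edges()
        density, score = cluster_score(n, e)
        clusters.append(
            Cluster(
                members=tuple(sorted(members, key=str)),
                fluffed=tuple(sorted(fluffed, key=str)),
                n=n,
                e=e,
                density=density,
                score=score,
                seed=seed,
            )
        )
    clusters.sort(key=lambda c: (-c.score, str(c.seed)))
    return clusters
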