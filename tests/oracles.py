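"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: centralities come from
explicit all-pairs shortest-path enumeration, the hypergeometric tail from
exhaustive subset enumeration, and the eigenvector from power iteration.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np


def brute_force_centralities(graph: nx.Graph) -> dict[str, dict]:
    """All six centralities by explicit enumeration (small graphs only)."""
    nodes = sorted(graph.nodes)
    degree = {v: graph.degree(v) for v in nodes}
    betweenness = dict.fromkeys(nodes, 0.0)
    stress = dict.fromkeys(nodes, 0)
    closeness = {}
    radiality = {}

    components = [sorted(c) for c in nx.connected_components(graph)]
    for members in components:
        sub = graph.subgraph(members)
        n_c = len(members)
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max((d for row in lengths.values() for d in row.values()), default=0)
        for v in members:
            total = sum(d for u, d in lengths[v].items() if u != v)
            closeness[v] = (n_c - 1) / total if total else 0.0
            radiality[v] = (
                sum(diam + 1 - d for u, d in lengths[v].items() if u != v) / (n_c - 1)
                if n_c > 1
                else 0.0
            )
        for s, t in combinations(members, 2):
            paths = list(nx.all_shortest_paths(sub, s, t))
            for v in members:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                if through:
                    stress[v] += through
                    betweenness[v] += through / len(paths)

    eigenvector = {}
    for members in components:
        if len(members) == 1:
            eigenvector[members[0]] = 1.0
            continue
        adjacency = nx.to_numpy_array(graph.subgraph(members), nodelist=members)
        # accelerated power iteration on A + I: the shift makes the Perron
        # eigenvalue strictly dominant even on bipartite components, and
        # repeated squaring ((A+I)^(2^k) v) converges doubly exponentially,
        # so small spectral gaps still reach machine precision
        shifted = adjacency + np.eye(len(members))
        for _ in range(60):
            shifted = shifted @ shifted
            shifted /= np.linalg.norm(shifted)
        vec = shifted @ np.ones(len(members))
        vec /= np.linalg.norm(vec)
        for node, value in zip(members, np.abs(vec)):
            eigenvector[node] = float(value)

    return {
        "degree": degree,
        "betweenness": betweenness,
        "closeness": closeness,
        "radiality": radiality,
        "stress": stress,
        "eigenvector": eigenvector,
    }


def hypergeom_upper_by_enumeration(
    obs: int, draws: int, successes_in_pop: int, pop: int
) -> float:
    """P(X >= obs) by enumerating every draw subset of a small population."""
    population = list(range(pop))
    successes = set(population[:successes_in_pop])
    total = 0
    favourable = 0
    for subset in combinations(population, draws):
        total += 1
        if len(successes.intersection(subset)) >= obs:
            favourable += 1
    return favourable / total
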