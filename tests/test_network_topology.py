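from __future__ import annotations

import math
import random

import networkx as nx
import numpy as np
import pytest

from deg_netprior.network_topology import (
    METRICS,
    composite_topology_score,
    compute_centralities,
    induced_subnetwork,
    select_round2,
)
from oracles import brute_force_centralities


def random_graph(rng: random.Random, n_max: int = 8) -> nx.Graph:
    n = rng.randint(2, n_max)
    p = rng.uniform(0.2, 0.9)
    graph = nx.Graph()
    graph.add_nodes_from(f"n{i}" for i in range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                graph.add_edge(f"n{i}", f"n{j}")
    return graph


class TestInducedSubnetwork:
    def test_triangle_restriction(self):
        triangle = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        sub = induced_subnetwork(triangle, {"A", "B"})
        assert set(sub.nodes) == {"A", "B"}
        assert list(sub.edges) == [("A", "B")]

    def test_disjoint_genes_give_empty_graph(self):
        triangle = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        sub = induced_subnetwork(triangle, {"X", "Y"})
        assert sub.number_of_nodes() == 0

    def test_edge_count_matches_double_loop(self):
        rng = random.Random(5)
        graph = random_graph(rng, n_max=12)
        genes = {v for v in graph.nodes if rng.random() < 0.6}
        sub = induced_subnetwork(graph, genes)
        expected = sum(
            1 for a, b in graph.edges if a in genes and b in genes
        )
        assert sub.number_of_edges() == expected


class TestCentralities:
    def test_path_graph_hand_enumeration(self):
        path = nx.Graph([("A", "B"), ("B", "C")])
        c = compute_centralities(path)
        assert c.loc["B", "degree"] == 2
        assert c.loc["B", "betweenness"] == pytest.approx(1.0)
        assert c.loc["B", "stress"] == 1
        assert c.loc["B", "closeness"] == pytest.approx(1.0)
        assert c.loc["B", "radiality"] == pytest.approx(2.0)

    def test_triangle_symmetry_and_eigenvector(self):
        triangle = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        c = compute_centralities(triangle)
        for metric in METRICS:
            assert c[metric].max() - c[metric].min() < 1e-12
        assert np.allclose(c["eigenvector"], 1 / math.sqrt(3))

    def test_star_center_dominates_leaves(self):
        star = nx.star_graph(4)
        scores = composite_topology_score(compute_centralities(star))
        center, leaves = scores.loc[0], scores.drop(index=0)
        assert (center["composite_score"] > leaves["composite_score"]).all()

    def test_singleton_component_conventions(self):
        graph = nx.Graph([("A", "B")])
        graph.add_node("Z")
        c = compute_centralities(graph)
        assert c.loc["Z", ["degree", "betweenness", "closeness", "radiality", "stress"]].eq(0).all()
        assert c.loc["Z", "eigenvector"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_agrees_with_brute_force_enumeration(self, seed):
        rng = random.Random(seed)
        graph = random_graph(rng)
        ours = compute_centralities(graph)
        oracle = brute_force_centralities(graph)
        for metric in METRICS:
            for node in graph.nodes:
                assert ours.loc[node, metric] == pytest.approx(
                    oracle[metric][node], abs=1e-9
                ), f"{metric} disagrees at {node}"

    def test_isomorphism_equivariance(self):
        rng = random.Random(42)
        graph = random_graph(rng)
        mapping = {v: f"x_{v}" for v in graph.nodes}
        relabeled = nx.relabel_nodes(graph, mapping)
        ours = composite_topology_score(compute_centralities(graph))
        theirs = composite_topology_score(compute_centralities(relabeled))
        for node in graph.nodes:
            assert ours.loc[node, "composite_score"] == pytest.approx(
                theirs.loc[mapping[node], "composite_score"]
            )

    def test_vertex_transitive_graph_scores_equal(self):
        cycle = nx.cycle_graph(7)
        scores = composite_topology_score(compute_centralities(cycle))
        assert scores["composite_score"].nunique() == 1


class TestRound2Selection:
    def test_inclusive_mark(self):
        import pandas as pd

        scores = pd.DataFrame(
            {"composite_score": [60.0, 50.0, 40.0]}, index=["a", "b", "c"]
        )
        assert select_round2(scores, 50) == {"a", "b"}
        assert select_round2(scores, 0) == {"a", "b", "c"}
        assert select_round2(scores, 50, below=True) == {"b", "c"}

    def test_selections_nested_in_mark(self):
        rng = random.Random(3)
        graph = random_graph(rng, n_max=12)
        scores = composite_topology_score(compute_centralities(graph))
        assert select_round2(scores, 80) <= select_round2(scores, 50)

    def test_maximal_node_has_composite_100(self):
        star = nx.star_graph(5)
        scores = composite_topology_score(compute_centralities(star))
        assert scores.loc[0, "composite_score"] == pytest.approx(100.0)
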