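from __future__ import annotations

import pytest

from deg_netprior.go_ranking import (
    average_percentile,
    build_rank_table,
    percentile_rank,
    score_genes,
    score_terms,
    screen_round1,
)
from deg_netprior.io_tables import AnnotationSet
from deg_netprior.synthetic_data import SyntheticSpec, generate


def _annotation_set(terms: dict[str, set[str]], pop: int, ns: str = "BP") -> AnnotationSet:
    annotations = AnnotationSet()
    for term_id, genes in terms.items():
        for gene in genes:
            annotations.add(term_id, ns, gene, len(genes), pop)
    return annotations


class TestTermScoring:
    def test_fold_enrichment_formula(self):
        # 5 of 50 regulated vs 100 of 10000 background -> (0.1)/(0.01) = 10
        annotations = AnnotationSet()
        regulated = {f"R{i}" for i in range(50)}
        members = {f"R{i}" for i in range(5)} | {f"X{i}" for i in range(5)}
        for gene in members:
            annotations.add("T1", "BP", gene, 100, 10000)
        [term] = score_terms(regulated, annotations, "BP")
        assert term.observed_count == 5
        assert term.go_score == pytest.approx(10.0)

    def test_saturation_identity(self):
        # every regulated gene annotated, term background = population
        regulated = {"a", "b", "c"}
        annotations = _annotation_set({"T1": set(regulated)}, pop=3)
        annotations.term_background["T1"] = 3
        [term] = score_terms(regulated, annotations, "BP")
        assert term.go_score == pytest.approx(1.0)

    def test_matches_independent_ratio_oracle(self, default_bundle):
        records, _, annotations, truth = default_bundle
        regulated = set(truth.up)
        for ns in ("BP", "CC", "MF"):
            for term in score_terms(regulated, annotations, ns):
                members = annotations.genes_of(term.term_id, ns)
                obs = sum(1 for g in regulated if g in members)
                expected = (obs / len(regulated)) / (
                    annotations.term_background[term.term_id]
                    / annotations.population_background
                )
                assert term.go_score == pytest.approx(expected)
                assert obs == term.observed_count

    def test_scale_invariance_of_go_score(self):
        base = (5, 50, 100, 10000)
        scores = []
        for factor in (1, 3, 7):
            obs, inp, term_bg, pop = (x * factor for x in base)
            scores.append((obs / inp) / (term_bg / pop))
        assert scores[0] == pytest.approx(scores[1]) == pytest.approx(scores[2])


class TestGeneScoring:
    def test_sums_admitted_terms(self):
        regulated = {f"R{i}" for i in range(10)}
        annotations = AnnotationSet()
        # two strongly enriched terms sharing gene R0
        for term_id, members in (
            ("T1", {"R0", "R1", "R2"}),
            ("T2", {"R0", "R3", "R4"}),
        ):
            for gene in members:
                annotations.add(term_id, "BP", gene, 3, 1000)
        terms = score_terms(regulated, annotations, "BP")
        assert all(t.admitted for t in terms)
        scores = score_genes(terms, annotations, regulated)
        by_id = {t.term_id: t.go_score for t in terms}
        assert scores["R0"] == pytest.approx(by_id["T1"] + by_id["T2"])
        assert scores["R1"] == pytest.approx(by_id["T1"])
        assert scores["R9"] == 0.0

    def test_non_admitted_terms_excluded(self):
        regulated = {f"R{i}" for i in range(3)} | {f"S{i}" for i in range(47)}
        annotations = AnnotationSet()
        # term covering 1 of 50 regulated genes out of a 400-gene background slice
        for gene in ["R0"] + [f"B{i}" for i in range(399)]:
            annotations.add("T_weak", "BP", gene, 400, 1000)
        terms = score_terms(regulated, annotations, "BP")
        assert not terms[0].admitted
        scores = score_genes(terms, annotations, regulated)
        assert scores["R0"] == 0.0

    def test_matches_explicit_double_loop(self, default_bundle):
        _, _, annotations, truth = default_bundle
        regulated = set(truth.up)
        terms = score_terms(regulated, annotations, "BP")
        admitted = [t for t in terms if t.admitted]
        scores = score_genes(admitted, annotations, regulated)
        for gene in regulated:
            expected = 0.0
            for term in admitted:
                if gene in annotations.genes_of(term.term_id, "BP"):
                    expected += term.go_score
            assert scores[gene] == pytest.approx(expected)


class TestPercentiles:
    def test_three_distinct_scores(self):
        ranks = percentile_rank({"a": 1.0, "b": 2.0, "c": 3.0})
        assert ranks["a"] == pytest.approx(100 / 3)
        assert ranks["b"] == pytest.approx(200 / 3)
        assert ranks["c"] == 100.0

    def test_single_gene_is_100(self):
        assert percentile_rank({"a": 5.0}) == {"a": 100.0}

    def test_all_ties_share_100(self):
        assert set(percentile_rank({"a": 2.0, "b": 2.0, "c": 2.0}).values()) == {100.0}

    def test_invariant_under_monotone_transform(self):
        scores = {"a": 0.5, "b": 1.5, "c": 1.5, "d": 9.0}
        transformed = {g: s**3 + 2 for g, s in scores.items()}
        assert percentile_rank(scores) == percentile_rank(transformed)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank({})

    def test_average_percentile(self):
        assert average_percentile({"BP": 90, "CC": 80, "MF": 70}) == pytest.approx(80)
        assert average_percentile({"BP": 90}) == pytest.approx(90)


class TestRound1Screen:
    def test_inclusive_boundary(self):
        import pandas as pd

        table = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "average_percentile": [85.0, 80.0, 79.0]}
        )
        assert screen_round1(table, 80) == {"a", "b"}
        assert screen_round1(table, 0) == {"a", "b", "c"}

    def test_selection_antitone_in_cutoff(self, default_bundle):
        _, _, annotations, truth = default_bundle
        table = build_rank_table(set(truth.up), annotations)
        assert screen_round1(table, 90) <= screen_round1(table, 80)
        assert screen_round1(table, 80) <= screen_round1(table, 50)

    def test_rank_table_percentile_bounds(self, default_bundle):
        _, _, annotations, truth = default_bundle
        table = build_rank_table(set(truth.up), annotations)
        assert not table.empty
        assert table["average_percentile"].between(0, 100).all()
        # genes only appear if they reached at least one namespace ranking
        per_ns = [c for c in table.columns if c.startswith("percentile_")]
        assert table[per_ns].notna().any(axis=1).all()
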