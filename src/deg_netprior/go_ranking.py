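"""Round-1 screening: GO enrichment-ratio scoring and percentile-band selection.

Each admitted GO term gets a fold-enrichment score

    go_score = (observed / input) / (term_background / population_background)

i.e. the observed fraction of the regulated set annotated to the term over the
background fraction. A gene's namespace score is the sum of go_score over the
admitted terms annotating it; per-namespace scores are turned into percentile
ranks, percentiles are averaged over the namespaces the gene occupies, and
genes at or above the cutoff band (default the 80th percentile) survive into
round 2.

Term admission mirrors consuming an enriched-category export: only terms whose
upper-tail hypergeometric p-value is at or below the admission threshold
(default 0.05) contribute to gene scoring.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import pandas as pd

from deg_netprior.enrichment_bingo import hypergeom_upper
from deg_netprior.io_tables import AnnotationSet


@dataclass(frozen=True)
class TermScore:
    term_id: str
    namespace: str
    observed_count: int
    input_count: int
    term_background_count: int
    population_background_count: int
    go_score: float
    p_value: float
    admitted: bool


def score_terms(
    regulated_genes: set[str],
    annotations: AnnotationSet,
    namespace: str,
    admission_p: float = 0.05,
) -> list[TermScore]:
    """Score every term of ``namespace`` hit by at least one regulated gene."""
    if not regulated_genes:
        raise ValueError("regulated gene set must be non-empty")
    input_count = len(regulated_genes)
    pop_bg = annotations.population_background
    scores: list[TermScore] = []
    for term_id in sorted(annotations.terms(namespace)):
        members = annotations.genes_of(term_id, namespace)
        observed = len(regulated_genes & members)
        if observed < 1:
            continue
        term_bg = annotations.term_background[term_id]
        if term_bg == 0:
            raise ValueError(f"term {term_id!r} has zero background count")
        go_score = (observed / input_count) / (term_bg / pop_bg)
        p = hypergeom_upper(
            observed, min(input_count, pop_bg), term_bg, pop_bg
        )
        scores.append(
            TermScore(
                term_id=term_id,
                namespace=namespace,
                observed_count=observed,
                input_count=input_count,
                term_background_count=term_bg,
                population_background_count=pop_bg,
                go_score=go_score,
                p_value=p,
                admitted=p <= admission_p,
            )
        )
    return scores


def score_genes(
    term_scores: list[TermScore],
    annotations: AnnotationSet,
    regulated_genes: set[str],
) -> dict[str, float]:
    """Per-gene summed go_score over admitted terms of one namespace.

    Genes annotated only to non-admitted terms score 0.
    """
    namespaces = {t.namespace for t in term_scores}
    if len(namespaces) > 1:
        raise ValueError("term_scores must all come from one namespace")
    scores = {g: 0.0 for g in regulated_genes}
    for term in term_scores:
        if not term.admitted:
            continue
        for gene in annotations.genes_of(term.term_id, term.namespace):
            if gene in scores:
                scores[gene] += term.go_score
    return scores


def percentile_rank(scores: dict[str, float]) -> dict[str, float]:
    """Inclusive empirical-CDF percentile: 100 * #(score <= s) / N.

    Tied scores share a percentile and the maximum scores rank 100, so a
    "top 20%" band always contains the best-scoring genes.
    """
    if not scores:
        raise ValueError("cannot percentile-rank an empty score map")
    values = sorted(scores.values())
    n = len(values)
    return {
        g: 100.0 * bisect.bisect_right(values, s) / n for g, s in scores.items()
    }


def average_percentile(per_namespace: dict[str, float]) -> float:
    """Mean percentile over the namespaces in which the gene is present."""
    if not per_namespace:
        raise ValueError("gene has no namespace percentile")
    return sum(per_namespace.values()) / len(per_namespace)


def build_rank_table(
    regulated_genes: set[str],
    annotations: AnnotationSet,
    admission_p: float = 0.05,
    cutoff_percentile: float = 80.0,
) -> pd.DataFrame:
    """Full round-1 table: per-namespace score/percentile, average, selection.

    A gene enters a namespace's ranking only if it is annotated to at least
    one admitted term there; its average percentile runs over the namespaces
    it occupies. Genes absent from every namespace are excluded.
    """
    per_ns_scores: dict[str, dict[str, float]] = {}
    per_ns_percentiles: dict[str, dict[str, float]] = {}
    for ns in annotations.namespaces():
        terms = score_terms(regulated_genes, annotations, ns, admission_p=admission_p)
        admitted = [t for t in terms if t.admitted]
        present = {
            g
            for t in admitted
            for g in annotations.genes_of(t.term_id, t.namespace)
            if g in regulated_genes
        }
        if not present:
            per_ns_scores[ns] = {}
            per_ns_percentiles[ns] = {}
            continue
        scores = score_genes(admitted, annotations, present)
        per_ns_scores[ns] = scores
        per_ns_percentiles[ns] = percentile_rank(scores)

    genes = sorted(set().union(*(per_ns_percentiles[ns] for ns in annotations.namespaces())))
    rows = []
    for gene in genes:
        row: dict[str, object] = {"gene_id": gene}
        present = {}
        for ns in annotations.namespaces():
            row[f"score_{ns}"] = per_ns_scores[ns].get(gene)
            pct = per_ns_percentiles[ns].get(gene)
            row[f"percentile_{ns}"] = pct
            if pct is not None:
                present[ns] = pct
        row["average_percentile"] = average_percentile(present)
        rows.append(row)
    table = pd.DataFrame(rows)
    if not table.empty:
        table["selected_round1"] = table["average_percentile"] >= cutoff_percentile
    else:
        table = pd.DataFrame(
            columns=["gene_id", "average_percentile", "selected_round1"]
        )
    return table


def screen_round1(
    rank_table: pd.DataFrame, cutoff_percentile: float = 80.0
) -> set[str]:
    """Genes whose average percentile is at or above the cutoff band."""
    if rank_table.empty:
        return set()
    keep = rank_table["average_percentile"] >= cutoff_percentile
    return set(rank_table.loc[keep, "gene_id"])
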