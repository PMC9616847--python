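"""GO over-representation testing on a gene set (BiNGO-style).

The test is the exact upper-tail hypergeometric: the probability of observing
at least ``obs`` annotated genes when ``draws`` genes are sampled without
replacement from a population of ``pop`` genes of which ``successes_in_pop``
carry the term. Terms are significant at raw p <= cutoff by default (the
common BiNGO setting); Benjamini-Hochberg adjustment is available behind the
``correction`` flag. The reference population is the annotation background,
not the network node set.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

from deg_netprior.io_tables import AnnotationSet


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    namespace: str
    observed: int
    expected: float
    p_value: float
    adjusted_p: float | None
    significant: bool


def hypergeom_upper(obs: int, draws: int, successes_in_pop: int, pop: int) -> float:
    """Exact P(X >= obs) for X ~ Hypergeometric(pop, successes_in_pop, draws).

    Computed with exact integer combinatorics (one big-integer tail sum and a
    single division), so the result is correct to the full double precision of
    the returned float rather than to the accumulation error of a
    floating-point pmf sum.
    """
    if obs < 0:
        raise ValueError("obs must be >= 0")
    if draws < 0 or successes_in_pop < 0 or pop < 0:
        raise ValueError("counts must be non-negative")
    if draws > pop or successes_in_pop > pop:
        raise ValueError("draws and successes_in_pop must not exceed pop")
    if obs > min(draws, successes_in_pop):
        raise ValueError("obs exceeds min(draws, successes_in_pop)")
    k_max = min(draws, successes_in_pop)
    numerator = sum(
        comb(successes_in_pop, k) * comb(pop - successes_in_pop, draws - k)
        for k in range(obs, k_max + 1)
    )
    denominator = comb(pop, draws)
    return float(Fraction(numerator, denominator))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment (monotone, capped at 1)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def enrich(
    genes: set[str],
    annotations: AnnotationSet,
    cutoff: float = 0.05,
    correction: str = "none",
    namespaces: tuple[str, ...] | None = None,
) -> list[EnrichmentResult]:
    """Test every term with at least one hit in ``genes`` for over-representation.

    ``draws`` is the size of the query set, ``pop`` the annotation background
    population. Results are sorted by p-value then term id.
    """
    if not genes:
        raise ValueError("gene set must be non-empty")
    if correction not in ("none", "BH"):
        raise ValueError(f"unknown correction {correction!r}")
    draws = len(genes)
    pop = annotations.population_background
    raw: list[tuple[str, str, int, float, float]] = []
    for ns in namespaces or annotations.namespaces():
        for term_id, members in annotations.terms(ns).items():
            observed = len(genes & members)
            if observed < 1:
                continue
            successes = annotations.term_background[term_id]
            p = hypergeom_upper(observed, draws, successes, pop)
            expected = draws * successes / pop
            raw.append((term_id, ns, observed, expected, p))
    p_values = [r[4] for r in raw]
    adjusted = bh_adjust(p_values) if correction == "BH" else [None] * len(raw)
    results = []
    for (term_id, ns, observed, expected, p), adj in zip(raw, adjusted):
        decision_p = adj if correction == "BH" else p
        results.append(
            EnrichmentResult(
                term_id=term_id,
                namespace=ns,
                observed=observed,
                expected=expected,
                p_value=p,
                adjusted_p=adj,
                significant=decision_p <= cutoff,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def significant_terms(results: list[EnrichmentResult]) -> set[str]:
    return {r.term_id for r in results if r.significant}


def compare_directions(
    up_terms: set[str], down_terms: set[str]
) -> tuple[set[str], set[str], set[str]]:
    """(shared, up-specific, down-specific) process sets."""
    shared = up_terms & down_terms
    return shared, up_terms - shared, down_terms - shared
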