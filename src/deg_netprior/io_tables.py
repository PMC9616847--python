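"""Readers/writers for the pipeline's tabular formats, plus percentage helpers.

All tables are UTF-8 TSV with a header row. Gene identifiers are opaque,
case-sensitive strings; no ortholog or accession mapping is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

VALID_CALLS = ("up", "down", "not_significant")
NAMESPACES = ("BP", "CC", "MF")


class TableFormatError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class TableValidationError(ValueError):
    """Parsed values violate a table invariant (duplicates, bad ranges)."""


@dataclass(frozen=True)
class DEGRecord:
    """One gene's differential-expression evidence and its regulation call."""

    gene_id: str
    log2fc: float
    fdr: float
    call: str = "not_significant"

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise TableValidationError(
                f"gene {self.gene_id!r}: fdr {self.fdr} outside [0, 1]"
            )
        if self.call not in VALID_CALLS:
            raise TableValidationError(
                f"gene {self.gene_id!r}: unknown call {self.call!r}"
            )


@dataclass
class AnnotationSet:
    """Flat gene<->GO-term memberships per namespace with background counts.

    ``term_genes[namespace][term_id]`` is the set of annotated gene ids;
    ``term_background[term_id]`` is the number of background-population genes
    carrying the term, and ``population_background`` the background population
    size. The GO DAG is not consulted: term-gene tables are treated as flat,
    the way STRING/BiNGO exports present them.
    """

    term_genes: dict[str, dict[str, set[str]]] = field(
        default_factory=lambda: {ns: {} for ns in NAMESPACES}
    )
    term_background: dict[str, int] = field(default_factory=dict)
    population_background: int = 0

    def add(
        self,
        term_id: str,
        namespace: str,
        gene_id: str,
        term_background_count: int,
        population_background_count: int,
    ) -> None:
        if namespace not in NAMESPACES:
            raise TableValidationError(
                f"term {term_id!r}: namespace {namespace!r} not one of {NAMESPACES}"
            )
        if term_background_count < 1:
            raise TableValidationError(
                f"term {term_id!r}: term_background_count must be >= 1"
            )
        if term_background_count > population_background_count:
            raise TableValidationError(
                f"term {term_id!r}: term background {term_background_count} exceeds "
                f"population background {population_background_count}"
            )
        prev = self.term_background.get(term_id)
        if prev is not None and prev != term_background_count:
            raise TableValidationError(
                f"term {term_id!r}: inconsistent background counts {prev} vs "
                f"{term_background_count}"
            )
        if self.population_background and (
            population_background_count != self.population_background
        ):
            raise TableValidationError(
                f"term {term_id!r}: inconsistent population background"
            )
        self.population_background = population_background_count
        self.term_background[term_id] = term_background_count
        self.term_genes[namespace].setdefault(term_id, set()).add(gene_id)

    def namespaces(self) -> tuple[str, ...]:
        return NAMESPACES

    def terms(self, namespace: str) -> dict[str, set[str]]:
        return self.term_genes[namespace]

    def genes_of(self, term_id: str, namespace: str) -> set[str]:
        return self.term_genes[namespace].get(term_id, set())

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for ns in NAMESPACES:
            for genes in self.term_genes[ns].values():
                out |= genes
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ns in NAMESPACES:
            for term_id in sorted(self.term_genes[ns]):
                for gene_id in sorted(self.term_genes[ns][term_id]):
                    rows.append(
                        (
                            term_id,
                            ns,
                            gene_id,
                            self.term_background[term_id],
                            self.population_background,
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=[
                "term_id",
                "namespace",
                "gene_id",
                "term_background_count",
                "population_background_count",
            ],
        )


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    """Read a DEG table (columns gene_id, log2fc, fdr, optional call).

    Non-numeric log2fc/fdr cells are rejected with the offending 1-based data
    row number; duplicate gene ids are a validation error.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("gene_id", "log2fc", "fdr"), path)
    records: list[DEGRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        gene_id = str(row.gene_id)
        try:
            log2fc = float(row.log2fc)
            fdr = float(row.fdr)
        except ValueError as exc:
            raise TableFormatError(
                f"{path}: non-numeric log2fc/fdr on row {i} (gene {gene_id!r})"
            ) from exc
        if gene_id in seen:
            raise TableValidationError(f"{path}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        call = getattr(row, "call", "not_significant") or "not_significant"
        records.append(DEGRecord(gene_id, log2fc, fdr, call))
    return records


def write_deg_table(records: Iterable[DEGRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, r.log2fc, r.fdr, r.call) for r in records],
        columns=["gene_id", "log2fc", "fdr", "call"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, score_min: float = 0.0) -> nx.Graph:
    """Read a STRING-style edge list into an undirected simple graph.

    Self-loops are dropped, edges below ``score_min`` are dropped, and
    duplicate unordered pairs (STRING exports list both orientations) collapse
    to one edge keeping the maximum combined score.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, ("node_a", "node_b", "combined_score"), path)
    graph = nx.Graph()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        a, b = str(row.node_a), str(row.node_b)
        try:
            score = float(row.combined_score)
        except ValueError as exc:
            raise TableFormatError(
                f"{path}: non-numeric combined_score on row {i}"
            ) from exc
        if a == b:
            continue
        if score < score_min:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["combined_score"] = max(graph[a][b]["combined_score"], score)
        else:
            graph.add_edge(a, b, combined_score=score)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), data.get("combined_score", 1.0))
        for a, b, data in graph.edges(data=True)
    )
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a gene->GO annotation table into an :class:`AnnotationSet`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(
        df,
        (
            "term_id",
            "namespace",
            "gene_id",
            "term_background_count",
            "population_background_count",
        ),
        path,
    )
    annotations = AnnotationSet()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            term_bg = int(row.term_background_count)
            pop_bg = int(row.population_background_count)
        except ValueError as exc:
            raise TableFormatError(
                f"{path}: non-integer background count on row {i}"
            ) from exc
        annotations.add(str(row.term_id), str(row.namespace), str(row.gene_id), term_bg, pop_bg)
    return annotations


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    annotations.to_frame().to_csv(path, sep="\t", index=False)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table (gene_id, condition, replicate, ct_target, ct_reference)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require_columns(
        df, ("gene_id", "condition", "replicate", "ct_target", "ct_reference"), path
    )
    bad = set(df["condition"]) - {"test", "calibrator"}
    if bad:
        raise TableValidationError(f"{path}: unknown condition value(s) {sorted(bad)}")
    for col in ("ct_target", "ct_reference"):
        values = pd.to_numeric(df[col], errors="coerce")
        finite = np.isfinite(values.to_numpy(dtype=float))
        if not finite.all() or not (values[finite] > 0).all():
            raise TableValidationError(f"{path}: {col} must be positive finite cycles")
        df[col] = values
    return df


def proportion_percent(part: int, whole: int) -> float:
    """Percentage 100*part/whole rounded half-up to two decimals.

    Mirrors how read-retention and length-class fractions are reported from
    integer counts, e.g. 96403161 of 96411054 processed reads -> 99.99.
    """
    if whole <= 0:
        raise ValueError("whole must be a positive integer")
    if part < 0 or part > whole:
        raise ValueError("part must satisfy 0 <= part <= whole")
    value = Decimal(100) * Decimal(part) / Decimal(whole)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def write_json(obj: Mapping, path: str | Path) -> None:
    import json

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
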