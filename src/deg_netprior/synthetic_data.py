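"""Synthetic DEG tables, PPI networks and GO annotations with ground truth.

The generator emulates the statistical structure the prioritization assumes:

* a DEG table in which a chosen fraction of genes is up-/down-regulated by
  construction (|log2fc| = 2 + |Normal(lfc_location, lfc_scale)| and
  FDR ~ U(0, fdr_sig_max)), so threshold screening recovers the planted sets
  exactly;
* an undirected PPI network with dense planted modules (pairwise edge
  probability p_in) embedded in a sparse Erdos-Renyi background (p_out),
  with STRING-like combined scores on the edges;
* flat GO annotations per namespace, including planted terms drawn
  preferentially from the up-regulated set so they are over-represented.

All randomness flows from the single spec seed; the same spec yields
byte-identical artifacts. Planted modules are drawn from the up-regulated
genes (dense complexes among prioritized genes, as the analysis expects) and
are disjoint unless overlap is explicitly allowed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from deg_netprior.io_tables import (
    AnnotationSet,
    DEGRecord,
    write_annotations,
    write_deg_table,
    write_edge_list,
)

DEFAULT_MODULES: tuple[tuple[int, float], ...] = ((10, 0.9), (6, 0.9))
DEFAULT_PLANTED_TERMS: tuple[tuple[str, int, float], ...] = (
    ("BP", 40, 0.5),
    ("MF", 30, 0.4),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic bundle.

    Defaults give a 500-gene universe with 15% up- and 18% down-regulated
    genes (slightly more down than up), regulated |log2fc| averaging ~2.9,
    two planted near-clique modules in a 2% background, and 30 GO terms per
    namespace of which two are deliberately enriched in the up set.
    """

    n_genes: int = 500
    frac_up: float = 0.15
    frac_down: float = 0.18
    lfc_location: float = 0.9
    lfc_scale: float = 0.6
    fdr_sig_max: float = 0.05
    modules: tuple[tuple[int, float], ...] = DEFAULT_MODULES
    p_out: float = 0.02
    n_terms: int = 30
    planted_terms: tuple[tuple[str, int, float], ...] = DEFAULT_PLANTED_TERMS
    allow_module_overlap: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        for name in ("frac_up", "frac_down", "p_out", "fdr_sig_max"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.frac_up + self.frac_down > 1.0:
            raise ValueError("frac_up + frac_down must not exceed 1")
        for size, p_in in self.modules:
            if size < 3:
                raise ValueError("module sizes must be >= 3 (2-core detectable)")
            if not 0.0 <= p_in <= 1.0:
                raise ValueError("module p_in must be in [0, 1]")
            if p_in <= self.p_out:
                raise ValueError("module p_in must exceed background p_out")
        total_module = sum(size for size, _ in self.modules)
        n_up = round(self.frac_up * self.n_genes)
        if not self.allow_module_overlap and total_module > max(n_up, 0):
            raise ValueError(
                f"disjoint modules need {total_module} up-regulated genes, "
                f"only {n_up} available"
            )
        for ns, size, frac in self.planted_terms:
            if ns not in ("BP", "CC", "MF"):
                raise ValueError(f"planted term namespace {ns!r} invalid")
            if size > self.n_genes:
                raise ValueError("planted term size exceeds n_genes")
            if not 0.0 <= frac <= 1.0:
                raise ValueError("planted term up-fraction must be in [0, 1]")
            if round(size * frac) > n_up:
                raise ValueError(
                    "planted term demands more up-regulated genes than exist"
                )


@dataclass(frozen=True)
class GroundTruth:
    up: frozenset[str]
    down: frozenset[str]
    modules: tuple[frozenset[str], ...]
    planted_terms: tuple[str, ...]

    def to_json(self) -> dict:
        return {
            "up": sorted(self.up),
            "down": sorted(self.down),
            "modules": [sorted(m) for m in self.modules],
            "planted_terms": list(self.planted_terms),
        }


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _regulated_lfc(rng: np.random.Generator, n: int, loc: float, scale: float):
    return 2.0 + np.abs(rng.normal(loc, scale, size=n))


def _deg_records(spec: SyntheticSpec, rng: np.random.Generator, genes: list[str]):
    n = spec.n_genes
    n_up = round(spec.frac_up * n)
    n_down = round(spec.frac_down * n)
    order = rng.permutation(n)
    up_idx = order[:n_up]
    down_idx = order[n_up : n_up + n_down]
    ns_idx = order[n_up + n_down :]

    log2fc = np.zeros(n)
    fdr = np.zeros(n)
    log2fc[up_idx] = _regulated_lfc(rng, n_up, spec.lfc_location, spec.lfc_scale)
    log2fc[down_idx] = -_regulated_lfc(rng, n_down, spec.lfc_location, spec.lfc_scale)
    fdr[up_idx] = rng.uniform(0.0, spec.fdr_sig_max, size=n_up)
    fdr[down_idx] = rng.uniform(0.0, spec.fdr_sig_max, size=n_down)

    # Null genes: most have sub-threshold fold changes; a fifth have large
    # fold changes but non-significant FDR, so both rejection routes occur.
    n_ns = len(ns_idx)
    big = rng.random(n_ns) < 0.2
    ns_lfc = rng.normal(0.0, 0.75, size=n_ns)
    while np.any(np.abs(ns_lfc) >= 2.0):
        redo = np.abs(ns_lfc) >= 2.0
        ns_lfc[redo] = rng.normal(0.0, 0.75, size=int(redo.sum()))
    ns_lfc[big] = np.sign(ns_lfc[big] + 1e-9) * (
        2.0 + np.abs(rng.normal(spec.lfc_location, spec.lfc_scale, size=int(big.sum())))
    )
    ns_fdr = rng.uniform(0.0, 1.0, size=n_ns)
    ns_fdr[big] = rng.uniform(0.05, 1.0, size=int(big.sum()))
    log2fc[ns_idx] = ns_lfc
    fdr[ns_idx] = ns_fdr

    calls = np.array(["not_significant"] * n, dtype=object)
    calls[up_idx] = "up"
    calls[down_idx] = "down"
    records = [
        DEGRecord(genes[i], float(log2fc[i]), float(fdr[i]), str(calls[i]))
        for i in range(n)
    ]
    up = frozenset(genes[i] for i in up_idx)
    down = frozenset(genes[i] for i in down_idx)
    return records, up, down


def _network(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    genes: list[str],
    up: frozenset[str],
) -> tuple[nx.Graph, tuple[frozenset[str], ...]]:
    n = spec.n_genes
    index = {g: i for i, g in enumerate(genes)}
    up_sorted = sorted(up)

    module_sets: list[frozenset[str]] = []
    pool = list(up_sorted)
    for size, _ in spec.modules:
        if spec.allow_module_overlap:
            chosen = rng.choice(up_sorted, size=size, replace=False)
        else:
            chosen_idx = rng.choice(len(pool), size=size, replace=False)
            chosen = [pool[i] for i in sorted(chosen_idx)]
            pool = [g for g in pool if g not in set(chosen)]
        module_sets.append(frozenset(str(g) for g in chosen))

    prob = np.full((n, n), spec.p_out)
    for (size, p_in), members in zip(spec.modules, module_sets):
        idx = np.array([index[g] for g in members])
        prob[np.ix_(idx, idx)] = p_in
    draws = rng.random((n, n))
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    adjacency = (draws < prob) & upper

    graph = nx.Graph()
    graph.add_nodes_from(genes)
    rows, cols = np.nonzero(adjacency)
    scores = np.round(rng.uniform(0.4, 1.0, size=len(rows)), 3)
    for r, c, s in zip(rows, cols, scores):
        graph.add_edge(genes[r], genes[c], combined_score=float(s))
    return graph, tuple(module_sets)


def _annotations(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    genes: list[str],
    up: frozenset[str],
) -> tuple[AnnotationSet, tuple[str, ...]]:
    annotations = AnnotationSet()
    pop = spec.n_genes
    up_sorted = sorted(up)
    non_up = sorted(set(genes) - up)
    planted_ids: list[str] = []
    for ns in ("BP", "CC", "MF"):
        for t in range(1, spec.n_terms + 1):
            term_id = f"GO_{ns}_{t:04d}"
            size = int(rng.integers(5, 61))
            members = rng.choice(genes, size=size, replace=False)
            for gene in members:
                annotations.add(term_id, ns, str(gene), size, pop)
        for ns_planted, size, frac in spec.planted_terms:
            if ns_planted != ns:
                continue
            term_id = f"GO_{ns}_planted_{len(planted_ids) + 1:02d}"
            n_from_up = round(size * frac)
            chosen_up = rng.choice(up_sorted, size=n_from_up, replace=False)
            chosen_rest = rng.choice(non_up, size=size - n_from_up, replace=False)
            for gene in list(chosen_up) + list(chosen_rest):
                annotations.add(term_id, ns, str(gene), size, pop)
            planted_ids.append(term_id)
    return annotations, tuple(planted_ids)


def generate(
    spec: SyntheticSpec,
) -> tuple[list[DEGRecord], nx.Graph, AnnotationSet, GroundTruth]:
    """Generate one bundle (DEG table, network, annotations, ground truth)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    records, up, down = _deg_records(spec, rng, genes)
    network, modules = _network(spec, rng, genes, up)
    annotations, planted = _annotations(spec, rng, genes, up)
    truth = GroundTruth(up=up, down=down, modules=modules, planted_terms=planted)
    return records, network, annotations, truth


def write_bundle(
    spec: SyntheticSpec, outdir: str | Path
) -> dict[str, Path]:
    """Generate and write the four artifacts as TSV/JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, network, annotations, truth = generate(spec)
    paths = {
        "deg": outdir / "deg.tsv",
        "edges": outdir / "edges.tsv",
        "annotations": outdir / "annotations.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_deg_table(records, paths["deg"])
    write_edge_list(network, paths["edges"])
    write_annotations(annotations, paths["annotations"])
    paths["ground_truth"].write_text(
        json.dumps(truth.to_json(), indent=2, sort_keys=True) + "\n"
    )
    return paths
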