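"""End-to-end orchestration: classify -> GO ranking -> topology -> MCODE -> enrichment.

The up- and down-regulated directions run as independent branches sharing
the network and annotations; they meet only in the final shared/specific
process comparison. The pipeline is a pure composition of the stage
functions — no hidden state — so identical config and inputs give identical
outputs, and every stage's selection is a subset of the previous stage's
gene universe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from deg_netprior import io_tables
from deg_netprior.deg_screen import classify_table, regulated_sets
from deg_netprior.enrichment_bingo import compare_directions, enrich, significant_terms
from deg_netprior.go_ranking import build_rank_table, screen_round1
from deg_netprior.mcode_cluster import MCODEParams, find_complexes
from deg_netprior.network_topology import (
    composite_topology_score,
    compute_centralities,
    induced_subnetwork,
    network_summary,
    select_round2,
)
from deg_netprior.qpcr_quant import summarize_ct_table

log = logging.getLogger("deg_netprior")


@dataclass
class RunConfig:
    """All inputs and thresholds for one run; defaults are the study settings."""

    deg_path: str
    edges_path: str
    annotations_path: str
    output_dir: str
    ct_path: str | None = None
    lfc_min: float = 2.0
    fdr_max: float = 0.05
    score_min: float = 0.0
    admission_p: float = 0.05
    round1_cutoff: float = 80.0
    round2_mark: float = 50.0
    round2_below: bool = False
    enrichment_cutoff: float = 0.05
    correction: str = "none"
    mcode: MCODEParams = field(default_factory=MCODEParams)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        mcode = raw.pop("mcode", None)
        config = cls(**raw)
        if mcode is not None:
            config.mcode = MCODEParams(**mcode)
        return config


def _run_direction(
    name: str,
    genes: set[str],
    network,
    annotations,
    config: RunConfig,
    outdir: Path,
) -> dict:
    branch: dict = {"n_input": len(genes)}
    if not genes:
        branch.update(
            n_round1=0, n_round2=0, round1=[], round2=[], clusters=[],
            enriched_terms=[], network={"nodes": 0, "edges": 0},
        )
        return branch

    rank_table = build_rank_table(
        genes,
        annotations,
        admission_p=config.admission_p,
        cutoff_percentile=config.round1_cutoff,
    )
    rank_table.to_csv(outdir / f"rank_go_{name}.tsv", sep="\t", index=False)
    round1 = screen_round1(rank_table, cutoff_percentile=config.round1_cutoff)
    log.info("[%s] round 1: %d of %d genes selected", name, len(round1), len(genes))

    subnetwork = induced_subnetwork(network, round1)
    branch["network"] = network_summary(subnetwork)
    if subnetwork.number_of_nodes() > 0:
        centralities = compute_centralities(subnetwork)
        scores = composite_topology_score(centralities)
        scores.to_csv(outdir / f"rank_topo_{name}.tsv", sep="\t")
        round2 = select_round2(
            scores, mark=config.round2_mark, below=config.round2_below
        )
    else:
        round2 = set()
    log.info("[%s] round 2: %d of %d genes selected", name, len(round2), len(round1))

    clusters = find_complexes(subnetwork, config.mcode)
    cluster_rows = [
        {
            "cluster": i + 1,
            "seed": c.seed,
            "n": c.n,
            "e": c.e,
            "density": c.density,
            "score": c.score,
            "members": ";".join(c.members),
            "fluffed": ";".join(c.fluffed),
        }
        for i, c in enumerate(clusters)
    ]
    pd.DataFrame(
        cluster_rows,
        columns=["cluster", "seed", "n", "e", "density", "score", "members", "fluffed"],
    ).to_csv(outdir / f"mcode_{name}.tsv", sep="\t", index=False)

    if round2:
        results = enrich(
            round2,
            annotations,
            cutoff=config.enrichment_cutoff,
            correction=config.correction,
        )
        enriched = significant_terms(results)
        pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "namespace": r.namespace,
                    "observed": r.observed,
                    "expected": r.expected,
                    "p_value": r.p_value,
                    "adjusted_p": r.adjusted_p,
                    "significant": r.significant,
                }
                for r in results
            ]
        ).to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
    else:
        enriched = set()
    log.info("[%s] enrichment: %d significant processes", name, len(enriched))

    branch.update(
        n_round1=len(round1),
        n_round2=len(round2),
        round1=sorted(round1),
        round2=sorted(round2),
        clusters=cluster_rows,
        enriched_terms=sorted(enriched),
    )
    return branch


def run_pipeline(config: RunConfig) -> dict:
    """Run the full two-round prioritization; returns (and writes) the report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    records = io_tables.read_deg_table(config.deg_path)
    records = classify_table(records, lfc_min=config.lfc_min, fdr_max=config.fdr_max)
    io_tables.write_deg_table(records, outdir / "deg_classified.tsv")
    up, down = regulated_sets(records)
    network = io_tables.read_edge_list(config.edges_path, score_min=config.score_min)
    annotations = io_tables.read_annotations(config.annotations_path)
    log.info(
        "inputs: %d DEG records (%d up / %d down), network %d nodes / %d edges",
        len(records), len(up), len(down),
        network.number_of_nodes(), network.number_of_edges(),
    )

    report: dict = {
        "config": asdict(config),
        "inputs": {
            "n_records": len(records),
            "n_up": len(up),
            "n_down": len(down),
            "network_nodes": network.number_of_nodes(),
            "network_edges": network.number_of_edges(),
            "population_background": annotations.population_background,
        },
        "up": _run_direction("up", up, network, annotations, config, outdir),
        "down": _run_direction("down", down, network, annotations, config, outdir),
    }

    shared, up_only, down_only = compare_directions(
        set(report["up"]["enriched_terms"]), set(report["down"]["enriched_terms"])
    )
    report["processes"] = {
        "shared": sorted(shared),
        "up_specific": sorted(up_only),
        "down_specific": sorted(down_only),
        "n_shared": len(shared),
        "n_up_specific": len(up_only),
        "n_down_specific": len(down_only),
    }

    if config.ct_path:
        ct = io_tables.read_ct_table(config.ct_path)
        rq = summarize_ct_table(ct)
        rq.to_csv(outdir / "qpcr_rq.tsv", sep="\t", index=False)
        report["qpcr"] = rq.to_dict(orient="records")

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
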