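"""Regulation calls from log2 fold change and FDR.

A gene is called up-regulated when log2fc >= lfc_min and fdr < fdr_max,
down-regulated when log2fc <= -lfc_min and fdr < fdr_max, otherwise
not significant. Fold-change bounds are inclusive, the FDR bound strict.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable

from deg_netprior.io_tables import DEGRecord


def classify_deg(
    record: DEGRecord, lfc_min: float = 2.0, fdr_max: float = 0.05
) -> str:
    """Return the regulation call for one record."""
    if record.fdr < fdr_max:
        if record.log2fc >= lfc_min:
            return "up"
        if record.log2fc <= -lfc_min:
            return "down"
    return "not_significant"


def classify_table(
    records: Iterable[DEGRecord], lfc_min: float = 2.0, fdr_max: float = 0.05
) -> list[DEGRecord]:
    """Re-call every record; returns new records with the call field set."""
    return [
        replace(r, call=classify_deg(r, lfc_min=lfc_min, fdr_max=fdr_max))
        for r in records
    ]


def regulated_sets(records: Iterable[DEGRecord]) -> tuple[set[str], set[str]]:
    """(up, down) gene-id sets from already-called records."""
    up = {r.gene_id for r in records if r.call == "up"}
    down = {r.gene_id for r in records if r.call == "down"}
    return up, down
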