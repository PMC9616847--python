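"""Relative quantification of qPCR validation genes (comparative Ct method).

RQ = 2^-ddCt with ddCt = (Ct_target - Ct_reference)_test
                        - (Ct_target - Ct_reference)_calibrator,
the Livak method against an endogenous control gene and a calibrator sample.
Replicates are averaged on the Ct scale (a geometric mean on the quantity
scale) before the differences are taken; the replicate SDs of the two dCt
values are combined in quadrature and reported as a fold-change interval.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def relative_quantity(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """RQ = 2^-ddCt from four threshold-cycle values."""
    values = (ct_target_test, ct_ref_test, ct_target_cal, ct_ref_cal)
    if not all(math.isfinite(v) for v in values):
        raise ValueError("all Ct values must be finite")
    dct_test = ct_target_test - ct_ref_test
    dct_cal = ct_target_cal - ct_ref_cal
    return 2.0 ** -(dct_test - dct_cal)


def summarize_ct_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene RQ with an SD-propagated fold-change interval.

    Expects columns gene_id, condition ("test"/"calibrator"), replicate,
    ct_target, ct_reference. Returns rq, ddct, sd_ddct, rq_low, rq_high.
    """
    rows = []
    for gene_id, group in ct_table.groupby("gene_id", sort=True):
        parts = {}
        for condition in ("test", "calibrator"):
            sub = group[group["condition"] == condition]
            if sub.empty:
                raise ValueError(f"gene {gene_id!r}: no {condition} measurements")
            dct = sub["ct_target"].to_numpy() - sub["ct_reference"].to_numpy()
            parts[condition] = (float(np.mean(dct)), float(np.std(dct, ddof=1)) if len(dct) > 1 else 0.0)
        ddct = parts["test"][0] - parts["calibrator"][0]
        sd = math.hypot(parts["test"][1], parts["calibrator"][1])
        rq = 2.0**-ddct
        rows.append(
            {
                "gene_id": gene_id,
                "ddct": ddct,
                "sd_ddct": sd,
                "rq": rq,
                "rq_low": 2.0 ** -(ddct + sd),
                "rq_high": 2.0 ** -(ddct - sd),
            }
        )
    return pd.DataFrame(rows)
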