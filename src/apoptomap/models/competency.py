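"""Per-cluster apoptosis-competency summaries.

Joins the per-cell MOMP-sensitivity and caspase-activity flags to the cell
clusters and reports, per cluster, the percentage of competent cells and
the high/low ratios (the headline comparison between "persister"-like and
apoptosis-primed phenotypes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _ratio(n_high: int, n_low: int) -> float:
    return float(n_high) / n_low if n_low else float("inf")


def cluster_competency_summary(labels, momp_sensitive, caspase_high) -> pd.DataFrame:
    """Per-cluster competency table.

    Parameters are aligned per-cell vectors: cluster labels, boolean
    MOMP-sensitivity flags and boolean high-caspase-activity (SC% > 25)
    flags. Returns one row per cluster with counts, percentages and
    high/low ratios (``inf`` when a denominator is zero). Counts across
    rows sum to the cohort size.
    """
    labels = np.asarray(labels)
    momp = np.asarray(momp_sensitive, dtype=bool)
    casp = np.asarray(caspase_high, dtype=bool)
    if not (labels.shape == momp.shape == casp.shape):
        raise ValueError("labels and flag vectors must be aligned")
    rows = []
    for c in np.unique(labels):
        sel = labels == c
        n = int(sel.sum())
        n_momp = int(momp[sel].sum())
        n_casp = int(casp[sel].sum())
        rows.append({
            "cluster": c,
            "n_cells": n,
            "pct_momp_sensitive": 100.0 * n_momp / n,
            "momp_high_low_ratio": _ratio(n_momp, n - n_momp),
            "pct_high_sc": 100.0 * n_casp / n,
            "sc_high_low_ratio": _ratio(n_casp, n - n_casp),
        })
    return pd.DataFrame(rows).set_index("cluster")
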