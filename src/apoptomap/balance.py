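"""Cohort-combining diagnostics.

When two retrospective cohorts are merged to mimic a randomised design, two
things need checking: (1) clinicopathological risk factors must be
independent of treatment arm (Pearson chi-square), with random
down-filtering of the over-represented T-stage level if not; and (2) the
per-marker intensity distributions must differ no more across cohorts than
across slides within a cohort, measured by pairwise Jensen-Shannon
divergence (JSD, base 2 so values lie in [0, 1]) with a Wilcoxon rank-sum
comparison of across- versus within-cohort divergences and
Benjamini-Hochberg adjustment over markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import jensenshannon

logger = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, cumulative minimum)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


def chi_square_balance(clinical: pd.DataFrame, factor: str):
    """Pearson chi-square test of a categorical risk factor against arm.

    No continuity correction is applied. Factor levels absent from the data
    are dropped with a warning. Returns ``(statistic, df, p)``.
    """
    if clinical["treated"].nunique() < 2:
        raise ValueError("both treatment arms must be present")
    tab = pd.crosstab(clinical[factor], clinical["treated"])
    empty = tab.index[(tab.sum(axis=1) == 0)]
    if len(empty):
        logger.warning("dropping empty factor level(s): %s", list(empty))
        tab = tab.loc[tab.sum(axis=1) > 0]
    stat, p, dof, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
    return float(stat), int(dof), float(p)


def balance_by_downsampling(clinical: pd.DataFrame, factor: str, level,
                            seed: int) -> pd.DataFrame:
    """Randomly drop patients with a given factor level from the larger arm
    until the level's counts are equal across arms.

    The removal set is reproducible under ``seed``; patients lacking the
    target level are never removed. Already-balanced input is returned
    unchanged (logged).
    """
    has_level = clinical[factor] == level
    counts = clinical.loc[has_level].groupby("treated").size()
    if len(counts) < 2 or counts.iloc[0] == counts.iloc[1]:
        logger.info("factor %s level %r already balanced; no-op", factor, level)
        return clinical.copy()
    larger_arm = counts.idxmax()
    n_remove = int(counts.max() - counts.min())
    pool = clinical.index[has_level & (clinical["treated"] == larger_arm)]
    rng = np.random.default_rng(seed)
    drop = rng.choice(pool.to_numpy(), size=n_remove, replace=False)
    logger.info("removing %d patients with %s=%r from arm %r", n_remove, factor, level, larger_arm)
    return clinical.drop(index=drop).reset_index(drop=True)


def jsd(p, q) -> float:
    """Jensen-Shannon divergence (base 2) between two histograms.

    Inputs are normalised to sum to one; the result is symmetric, zero iff
    the histograms coincide and at most 1 (disjoint supports).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.size == 0 or q.size == 0 or p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("histograms must be non-empty with positive mass")
    if p.shape != q.shape:
        raise ValueError("histograms must share a common binning")
    # scipy returns the JS *distance* = sqrt(divergence)
    return float(jensenshannon(p, q, base=2) ** 2)


@dataclass
class DivergenceReport:
    """Per-marker within/across-cohort slide divergences and test results."""

    table: pd.DataFrame  # marker, n_within, n_across, median_within, median_across,
    #                      statistic, p, p_adjusted
    within: dict[str, np.ndarray]
    across: dict[str, np.ndarray]


def _slide_histograms(values_by_slide: dict, edges: np.ndarray, eps: float) -> dict:
    out = {}
    for slide, vals in values_by_slide.items():
        h, _ = np.histogram(vals, bins=edges)
        h = h.astype(float) + eps
        out[slide] = h / h.sum()
    return out


def slide_divergence_test(table, n_bins: int = 64, eps: float = 1e-12) -> DivergenceReport:
    """Compare across-cohort with within-cohort slide distribution distances.

    Per marker, each slide's cell intensities are histogrammed on a common
    64-bin grid spanning the pooled 0.5-99.5 percentile range; all pairwise
    slide JSDs are computed, split into within-cohort and across-cohort
    pairs, compared by a two-sided Wilcoxon rank-sum test, and BH-adjusted
    over markers.
    """
    df = table.data
    cohorts = df["cohort"].unique()
    if len(cohorts) < 2:
        raise ValueError("slide divergence test needs two cohorts")
    slide_cohort = df.drop_duplicates("slide_id").set_index("slide_id")["cohort"]
    for c in cohorts:
        if (slide_cohort == c).sum() < 2:
            raise ValueError(f"cohort {c!r} has fewer than 2 slides")

    rows, within_all, across_all = [], {}, {}
    for m in table.markers:
        lo, hi = np.percentile(df[m], [0.5, 99.5])
        if hi <= lo:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, n_bins + 1)
        hists = _slide_histograms(
            {s: g[m].to_numpy() for s, g in df.groupby("slide_id")}, edges, eps)
        within, across = [], []
        for s1, s2 in combinations(sorted(hists), 2):
            d = jsd(hists[s1], hists[s2])
            (within if slide_cohort[s1] == slide_cohort[s2] else across).append(d)
        within = np.asarray(within)
        across = np.asarray(across)
        stat, p = stats.ranksums(across, within)
        rows.append({"marker": m, "n_within": within.size, "n_across": across.size,
                     "median_within": float(np.median(within)),
                     "median_across": float(np.median(across)),
                     "statistic": float(stat), "p": float(p)})
        within_all[m], across_all[m] = within, across

    out = pd.DataFrame(rows)
    out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return DivergenceReport(table=out, within=within_all, across=across_all)
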