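"""Outcome analyses: arm-stratified Cox models, Kaplan-Meier curves and
cluster-clinical association tests.

Continuous per-patient features (cluster proportions or mean marker
intensities) are dichotomised at the median (ties to "low", so "high"
means strictly above the median) and fitted in proportional-hazards models
within each treatment arm separately — arms are never pooled. Univariate
fits are Benjamini-Hochberg-adjusted across features; multivariable fits
adjust for sex and age. Ties in event times are handled with Efron's
partial likelihood (the lifelines default), appropriate for recurrence
times recorded in months.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .balance import bh_adjust

logger = logging.getLogger(__name__)


def dichotomize_at_median(values) -> tuple[np.ndarray, float]:
    """Binary high/low split at the median; ties at the median go to low.

    Returns ``(flags, cut)`` with ``flags[i] = value > median``. All-equal
    input raises (no split exists).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to dichotomise")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: no median split")
    cut = float(np.median(x))
    return x > cut, cut


@dataclass
class CoxFitResult:
    """A fitted proportional-hazards model summary."""

    terms: pd.DataFrame  # index term; columns HR, ci_low, ci_high, p
    model_p: float
    aic: float
    concordance: float
    n: int
    events: int
    fitter: CoxPHFitter | None = field(default=None, repr=False)


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> CoxFitResult:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df[["time", "event", *covariates]], duration_col="time", event_col="event")
    s = cph.summary
    terms = pd.DataFrame({
        "HR": s["exp(coef)"],
        "ci_low": s["exp(coef) lower 95%"],
        "ci_high": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    model_p = float(cph.log_likelihood_ratio_test().p_value)
    return CoxFitResult(terms=terms, model_p=model_p, aic=float(cph.AIC_partial_),
                        concordance=float(cph.concordance_index_),
                        n=len(df), events=int(df["event"].sum()), fitter=cph)


def _arm_frame(clinical: pd.DataFrame, arm: str) -> pd.DataFrame:
    if arm not in ("treated", "surgery"):
        raise ValueError("arm must be 'treated' or 'surgery'")
    sel = clinical["treated"].astype(bool) if arm == "treated" else ~clinical["treated"].astype(bool)
    df = clinical.loc[sel].copy()
    if df["event"].sum() < 1:
        raise ValueError(f"no events in the {arm} arm")
    return df


def cox_univariate(features: pd.DataFrame, clinical: pd.DataFrame, arm: str,
                   dichotomize: bool = True) -> pd.DataFrame:
    """Per-feature single-covariate Cox fits within one arm, BH-adjusted.

    ``features`` is indexed by patient_id (cluster proportions or mean
    marker intensities); each column is median-dichotomised within the arm
    (unless ``dichotomize=False``) and fitted alone. Returns one row per
    feature with HR, CI, p, BH-adjusted p; features that fail to fit (e.g.
    complete separation) are flagged with NaN and an unbounded CI.
    """
    df = _arm_frame(clinical, arm).set_index("patient_id")
    rows = []
    for feat in features.columns:
        vals = features[feat].reindex(df.index)
        sub = df[["time", "event"]].copy()
        try:
            if dichotomize:
                flags, cut = dichotomize_at_median(vals.to_numpy())
                sub["x"] = flags.astype(float)
            else:
                cut = np.nan
                sub["x"] = vals.to_numpy(float)
            fit = _fit_cox(sub, ["x"])
            t = fit.terms.loc["x"]
            rows.append({"feature": feat, "cut": cut, "HR": t["HR"],
                         "ci_low": t["ci_low"], "ci_high": t["ci_high"],
                         "p": t["p"], "n": fit.n, "events": fit.events})
        except Exception as exc:  # noqa: BLE001 - separation/convergence
            logger.warning("univariate Cox failed for %s: %s", feat, exc)
            rows.append({"feature": feat, "cut": np.nan, "HR": np.nan,
                         "ci_low": 0.0, "ci_high": np.inf, "p": np.nan,
                         "n": len(df), "events": int(df["event"].sum())})
    out = pd.DataFrame(rows).set_index("feature")
    ok = out["p"].notna()
    out["p_adjusted"] = np.nan
    out.loc[ok, "p_adjusted"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def cox_multivariable(features: pd.DataFrame, clinical: pd.DataFrame, arm: str,
                      adjusters: tuple[str, ...] = ("sex", "age"),
                      dichotomize: bool = True) -> CoxFitResult:
    """Joint Cox fit of (dichotomised) features plus clinical adjusters.

    Categorical adjusters are dummy-coded; collinear columns are dropped
    with a warning before fitting.
    """
    df = _arm_frame(clinical, arm).set_index("patient_id")
    design = df[["time", "event"]].copy()
    for feat in features.columns:
        vals = features[feat].reindex(df.index).to_numpy()
        design[feat] = (dichotomize_at_median(vals)[0].astype(float)
                        if dichotomize else vals.astype(float))
    for adj in adjusters:
        col = df[adj]
        if col.dtype == object or str(col.dtype) == "category":
            dummies = pd.get_dummies(col, prefix=adj, drop_first=True, dtype=float)
            design = pd.concat([design, dummies], axis=1)
        else:
            design[adj] = col.astype(float)

    covs = [c for c in design.columns if c not in ("time", "event")]
    x = design[covs].to_numpy(float)
    keep, dropped = [], []
    for i, c in enumerate(covs):
        trial = x[:, [*(covs.index(k) for k in keep), i]]
        if np.linalg.matrix_rank(trial) == trial.shape[1] and np.ptp(x[:, i]) > 0:
            keep.append(c)
        else:
            dropped.append(c)
    if dropped:
        logger.warning("dropping collinear/constant covariate(s): %s", dropped)
    return _fit_cox(design, keep)


def stepwise_select(candidates: pd.DataFrame, clinical: pd.DataFrame, arm: str,
                    p_enter: float = 0.15, p_stay: float = 0.15,
                    dichotomize: bool = True) -> list[str]:
    """Forward-backward covariate selection on partial-likelihood p-values.

    At each forward step the candidate with the smallest Wald p below
    ``p_enter`` joins the model; backward steps drop any included term
    whose p rises above ``p_stay``. Deterministic given the input column
    order (ties broken by order).
    """
    df = _arm_frame(clinical, arm).set_index("patient_id")
    design = df[["time", "event"]].copy()
    for feat in candidates.columns:
        vals = candidates[feat].reindex(df.index).to_numpy()
        design[feat] = (dichotomize_at_median(vals)[0].astype(float)
                        if dichotomize else vals.astype(float))

    def term_p(selected: list[str]) -> pd.Series:
        fit = _fit_cox(design, selected)
        return fit.terms["p"]

    selected: list[str] = []
    remaining = list(candidates.columns)
    while remaining:
        best, best_p = None, p_enter
        for feat in remaining:
            try:
                p = term_p([*selected, feat]).loc[feat]
            except Exception:  # noqa: BLE001
                continue
            if p < best_p:
                best, best_p = feat, p
        if best is None:
            break
        selected.append(best)
        remaining.remove(best)
        # backward pass
        while len(selected) > 1:
            ps = term_p(selected)
            worst = ps.idxmax()
            if ps.loc[worst] > p_stay:
                selected.remove(worst)
                remaining.append(worst)
            else:
                break
    return selected


@dataclass
class KmCurve:
    """Product-limit estimates per group plus a log-rank comparison."""

    curves: dict[object, pd.DataFrame]  # group -> (time, survival, at_risk)
    logrank_stat: float | None
    logrank_p: float | None


def kaplan_meier(times, events, groups=None) -> KmCurve:
    """Kaplan-Meier estimates (and a log-rank test when >= 2 groups)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.zeros(times.size) if groups is None else np.asarray(groups)
    curves = {}
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        km = KaplanMeierFitter()
        km.fit(times[sel], events[sel])
        tab = km.event_table
        curves[g] = pd.DataFrame({
            "time": km.survival_function_.index.to_numpy(),
            "survival": km.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": tab["at_risk"].reindex(km.survival_function_.index).to_numpy(),
        })
    if len(curves) >= 2:
        res = multivariate_logrank_test(times, groups, events)
        return KmCurve(curves=curves, logrank_stat=float(res.test_statistic),
                       logrank_p=float(res.p_value))
    return KmCurve(curves=curves, logrank_stat=None, logrank_p=None)


def cluster_clinical_association(profiles: pd.DataFrame, clinical: pd.DataFrame,
                                 continuous: tuple[str, ...] = ("age",),
                                 categorical: tuple[str, ...] = ("sex", "t_stage", "grade", "location"),
                                 ) -> pd.DataFrame:
    """Associate cluster proportions with clinical covariates.

    Spearman correlation for continuous covariates, Kruskal-Wallis across
    covariate levels for categorical ones; BH adjustment over all tests.
    Constant covariates are skipped with a warning.
    """
    cl = clinical.set_index("patient_id").reindex(profiles.index)
    prop_cols = [c for c in profiles.columns if c.startswith("cluster_")]
    rows = []
    for pc in prop_cols:
        x = profiles[pc].to_numpy(float)
        for cov in continuous:
            v = cl[cov].to_numpy(float)
            if np.ptp(v[~np.isnan(v)]) == 0:
                logger.warning("constant covariate %s skipped", cov)
                continue
            rho, p = stats.spearmanr(x, v, nan_policy="omit")
            rows.append({"proportion": pc, "covariate": cov, "test": "spearman",
                         "statistic": float(rho), "p": float(p)})
        for cov in categorical:
            levels = [x[(cl[cov] == lv).to_numpy()] for lv in cl[cov].dropna().unique()]
            levels = [g for g in levels if g.size > 0]
            if len(levels) < 2:
                logger.warning("covariate %s has <2 levels; skipped", cov)
                continue
            if all(np.ptp(np.concatenate(levels)) == 0 for _ in [0]):
                logger.warning("constant covariate %s skipped", cov)
                continue
            stat, p = stats.kruskal(*levels)
            rows.append({"proportion": pc, "covariate": cov, "test": "kruskal",
                         "statistic": float(stat), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = bh_adjust(out["p"].to_numpy())
    return out
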