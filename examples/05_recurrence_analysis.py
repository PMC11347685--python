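"""Arm-stratified recurrence analysis of patient cluster profiles.

Simulates a cohort whose treated-arm recurrence hazard rises with the
cluster-2 ("persister") proportion and falls with cluster-4, then runs the
outcome pipeline: median-dichotomised univariate Cox per cluster with BH
adjustment, a multivariable model adjusted for sex and age, and
Kaplan-Meier curves. The effect appears in the treated arm only.
"""

import numpy as np
import pandas as pd

from apoptomap.survival import (
    cox_multivariable,
    cox_univariate,
    dichotomize_at_median,
    kaplan_meier,
)
from apoptomap.synthetic import SyntheticConfig, simulate_survival

cfg = SyntheticConfig(n_patients=400, n_treated=200, log_hr_cluster2=3.0,
                      log_hr_cluster4=-3.0, rng_seed=21)
rng = np.random.default_rng(cfg.rng_seed)
props = pd.DataFrame(rng.dirichlet([0.8] * 6, size=cfg.n_patients),
                     columns=[f"cluster_{i}" for i in range(1, 7)],
                     index=[f"P{i:04d}" for i in range(cfg.n_patients)])
treated = {p: i < cfg.n_treated for i, p in enumerate(props.index)}
clin = simulate_survival(props, treated, cfg, seed=22)

for arm in ("treated", "surgery"):
    res = cox_univariate(props, clin, arm=arm)
    print(f"\nunivariate Cox, {arm} arm (high = above-median proportion):")
    print(res[["HR", "ci_low", "ci_high", "p", "p_adjusted"]].round(3).to_string())

fit = cox_multivariable(props[["cluster_2", "cluster_4"]], clin, arm="treated")
print("\nmultivariable model (treated arm, adjusted for sex and age):")
print(fit.terms.round(3).to_string())
print(f"model p={fit.model_p:.2e}, AIC={fit.aic:.1f}, concordance={fit.concordance:.2f}")

flags, cut = dichotomize_at_median(
    props.loc[[p for p, t in treated.items() if t], "cluster_2"].to_numpy())
sel = clin["treated"]
km = kaplan_meier(clin.loc[sel, "time"], clin.loc[sel, "event"],
                  np.where(flags, "high cluster 2", "low cluster 2"))
print(f"\nKaplan-Meier, treated arm split at cluster-2 median ({cut:.3f}): "
      f"log-rank p = {km.logrank_p:.4f}")
print("high-cluster-2 treated patients recur faster; the surgery arm shows no split")
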