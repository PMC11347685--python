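# apoptomap

Single-cell apoptosis-competency profiling for multiplexed-imaging cohorts
of stage II colorectal cancer (CRC).

Whether a tumour cell dies under chemotherapy depends on a network of
intrinsic- and extrinsic-pathway proteins, not on any single marker.
`apoptomap` implements an analysis that works at the level of that
network: starting from a segmented-cell table of per-cell intensities for
16 apoptosis proteins (SMAC, XIAP, APAF1, procaspase-9/-3/-8, MCL-1,
BCL-XL, BCL2, BAX, BAK, FADD, FLIP, RIP3, CIAP1, BID), it

1. applies cell-level **QC** (nuclei count, compartment areas, staining
   alignment), log2 transform and slide-median normalisation;
2. checks **cohort combinability** (chi-square risk-factor balance with
   random down-filtering; per-marker Jensen-Shannon divergence of slide
   distributions, within- vs across-cohort, Wilcoxon + BH);
3. discovers **cell phenotypes** by K-means over k = 2…15 with
   consensus-clustering model selection via PAC (proportion of
   ambiguously clustered pairs) and Davies-Bouldin marker down-selection;
4. classifies per-cell **apoptosis competency** with two ODE models —
   MOMP sensitivity from BCL2-family stoichiometry (pore % at a 200 nM
   stress dose; minimal dose required for MOMP, η) and caspase-3
   activation downstream of MOMP (substrate cleavage %, SC > 25% = high
   activity) — after calibrating intensities to μM;
5. associates patient-level **phenotype proportions with recurrence**:
   median-dichotomised per-arm Cox models with BH adjustment,
   multivariable models adjusted for sex and age, stepwise selection,
   Kaplan-Meier/log-rank.

The scientific question the pipeline addresses: tumours dominated by a
"persister" phenotype — high XIAP, high SMAC, low procaspase-3 — have
ordinary MOMP sensitivity but inhibited executioner-caspase activation,
and patients carrying many such cells recur after adjuvant chemotherapy
despite (or because of) treatment, while showing no excess risk under
surgery alone.

Because the patient data for such analyses are restricted, the package
includes a first-class synthetic-cohort generator (`apoptomap.synthetic`)
with planted phenotype centroids, slide batch effects, Dirichlet
patient compositions and proportional-hazards outcomes; all recovery
properties are validated against its ground truth. See
[docs/methods.md](docs/methods.md) for the models, assumptions and
parameter choices.

## Worked example

`examples/` holds one short script per capability. Phenotype discovery
(`python examples/03_cluster_phenotypes.py`) on a ~2000-cell synthetic
cohort with six planted phenotypes prints:

```
PAC by k: {2: 0.0258, 3: 0.2277, 4: 0.2876, 5: 0.0274, 6: 0.0038,
           7: 0.0698, 8: 0.0978, 9: 0.1179, 10: 0.1362}
selected k = 6 (planted: 6)
adjusted Rand index vs planted labels: 0.962 (1 = perfect recovery)
```

PAC is minimised at the planted k = 6 (consensus is ambiguous for barely
3.8 per mille of cell pairs there) and the recovered labels agree with
the planted truth almost perfectly. Competency modelling
(`python examples/04_competency_models.py`) then yields, per phenotype:

```
         n_cells  pct_momp_sensitive  momp_high_low_ratio  pct_high_sc  sc_high_low_ratio
cluster
1             78               94.87                18.50        92.31              12.00
2             74               52.70                 1.11        82.43               4.69
...
4             23                0.00                 0.00        95.65              22.00

reference-profile check: 10.1% of SMAC is XIAP-bound at cleavage onset
(model calibration anchor ~10%)
```

Phenotype 2 — the "persister" profile — has unremarkable MOMP sensitivity
but the lowest share of cells with high caspase-3 activity (SC > 25%),
while phenotype 4 executes apoptosis almost uniformly. The recurrence
stage (`python examples/05_recurrence_analysis.py`) recovers the planted
outcome structure: high cluster-2 proportion carries HR ≈ 2.9
(p < 0.001) in the chemotherapy-treated arm and no significant effect in
the surgery-only arm.

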