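# Caspase-activation model: default parameter set (version 1).
# Units: concentrations in uM, time in minutes; bimolecular rates in
# 1/(uM*min), unimolecular in 1/min.
#
# Provenance: minimal reaction scheme calibrated once against two anchors —
# (a) about 10% of total SMAC bound to XIAP at the onset of substrate
# cleavage at the reference concentration profile, and (b) a substrate-
# cleavage distribution straddling the 25% competency threshold on
# CRC-like concentration spreads.
rates:
  k_apop: 0.5          # APAF1 -> apoptosome; cytochrome c non-limiting
  k_holo_f: 10.0       # apoptosome + procaspase-9 association
  k_holo_r: 0.5
  k_c3_cleave: 30.0    # holoenzyme cleaves procaspase-3
  k_c3_by_c9c: 1.0     # free cleaved caspase-9 (weaker) cleaves procaspase-3
  k_fb: 5.0            # caspase-3 feedback cleavage of procaspase-9
  k_x_c3_f: 50.0       # XIAP binds caspase-3 (tight)
  k_x_c3_r: 0.1
  k_x_holo_f: 20.0     # XIAP binds holoenzyme
  k_x_holo_r: 0.1
  k_smac_f: 1.4        # SMAC binds free XIAP
  k_smac_r: 0.02
  k_derepress_c3: 1.0  # SMAC displaces XIAP from XIAP:caspase-3
  k_derepress_holo: 1.0
  k_deg: 2.0           # XIAP-mediated caspase-3 degradation
  k_sub: 10.0          # caspase-3 substrate cleavage
substrate_total: 1.0   # reporter substrate pool, uM
horizon: 60.0          # minutes after MOMP
sc_threshold_pct: 25.0 # SC% above this = high caspase-3 activity
onset_frac: 0.01       # cleavage onset: cleaved substrate > 1% of total

# Reference concentration profile (uM): the calibration anchor cell.
# APAF1 fixed at the cohort median (not limiting for apoptosome formation).
reference_concentrations_uM:
  apaf1: 0.123
  pc3: 0.20
  pc9: 0.02
  smac: 0.40
  xiap: 0.10

# Quantile grids (lognormal around the reference medians, log2-SD 2 — the
# order-of-magnitude per-protein spread of tumour cohorts) for the monotone
# intensity->uM alignment of the caspase model inputs.
reference_quantiles:
  PC3:
    probs: [0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99]
    quantiles_uM: [0.007951, 0.020452, 0.033842, 0.078514, 0.2, 0.509464, 1.181955, 1.955828, 5.03073]
  PC9:
    probs: [0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99]
    quantiles_uM: [0.000795, 0.002045, 0.003384, 0.007851, 0.02, 0.050946, 0.118195, 0.195583, 0.503073]
  SMAC:
    probs: [0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99]
    quantiles_uM: [0.015902, 0.040903, 0.067684, 0.157028, 0.4, 1.018928, 2.36391, 3.911655, 10.061459]
  XIAP:
    probs: [0.01, 0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99]
    quantiles_uM: [0.003976, 0.010226, 0.016921, 0.039257, 0.1, 0.254732, 0.590977, 0.977914, 2.515365]
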