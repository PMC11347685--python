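# MOMP-sensitivity model: default parameter set (version 1).
# Units: concentrations in uM, time in minutes; bimolecular rates in
# 1/(uM*min), unimolecular in 1/min.
#
# Provenance: minimal BCL2-family competition scheme; guardian affinities
# are species-specific (BCL-XL tightest, MCL-1 loosest here) and the scheme
# is calibrated so that a 200 nM population-mean stress dose separates
# sensitive from insensitive cells across CRC-like concentration spreads.
stress_dose: 0.2        # uM (200 nM population-mean stress)
horizon: 180.0          # minutes
pore_threshold_pct: 10.0  # pores below this at the reference dose = low sensitivity
rates:
  k_act: 1.0            # stress-catalysed effector (BAX/BAK) activation
  k_pore: 10.0          # active-effector dimerisation into pores
  binding:              # reversible sequestration by each guardian
    BCL2:  {kf_stress: 10.0, kr_stress: 0.10, kf_effector: 10.0, kr_effector: 0.10}
    BCLXL: {kf_stress: 10.0, kr_stress: 0.05, kf_effector: 10.0, kr_effector: 0.05}
    MCL1:  {kf_stress: 10.0, kr_stress: 0.20, kf_effector: 10.0, kr_effector: 0.20}

# Reference cell-line concentration profile (uM): synthetic calibration
# defaults standing in for cell-line anchors measured alongside a cohort.
reference_concentrations_uM:
  bax: 0.20
  bak: 0.15
  bcl2: 0.10
  bclxl: 0.10
  mcl1: 0.05

# Linear intensity->uM anchors: a cell at the reference mean intensity
# receives the reference concentration. Intensities are arbitrary units on
# a 2^10 scale.
reference_anchors:
  BAX:   {mean_intensity: 1024.0, uM: 0.20}
  BAK:   {mean_intensity: 1024.0, uM: 0.15}
  BCL2:  {mean_intensity: 1024.0, uM: 0.10}
  BCLXL: {mean_intensity: 1024.0, uM: 0.10}
  MCL1:  {mean_intensity: 1024.0, uM: 0.05}
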