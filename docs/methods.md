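# Methods

`apoptomap` implements a single-cell apoptosis-competency analysis for
multiplexed immunofluorescence cohorts of stage II colorectal cancer
(CRC). The pipeline starts from a segmented-cell intensity table (image
acquisition, registration and segmentation are upstream) and ends with
treatment-arm-stratified recurrence statistics on patient-level cell-
phenotype profiles. Because the patient data such analyses are run on are
restricted, the package ships a synthetic-cohort generator that reproduces
the statistical structure the analysis assumes; every pipeline stage is
validated against that generator's planted ground truth.

## Cell table, QC and normalisation (`cell_table`)

One row per segmented cell: identifiers (cell, patient, slide, core,
cohort), spatial position, nuclei count, per-compartment areas (pixels),
a per-staining-round alignment quality in [0, 1], and one intensity column
per marker (arbitrary units, non-negative). Quality control keeps cells
with 1–2 nuclei, all three compartment areas strictly inside (10, 1500)
pixels (strict bounds: the rule is read literally as 10 < area < 1500),
and alignment ≥ a cohort-specific minimum (default 0.80, with 0.85 used
for cohorts with stricter registration). Cells failing several rules are
reported under the first failing rule in the fixed order nuclei → area →
alignment; removal itself is order-independent, and QC is idempotent.

Intensities are log2-transformed with a pseudocount of 1.0 (keeps zero
intensities defined; zero maps to zero). Slide batch effects are removed
by per-marker median centring in log2 space — subtract the slide median,
add back the global marker median — which preserves within-slide ordering
and each marker's global median, and is idempotent to numerical
tolerance. This is a deliberately simple, monotone stand-in for
proprietary normalisation procedures; slides with fewer than two cells
pass through unshifted. Patient-level marker means pool all of a
patient's cells across cores (cell-weighted, not core-averaged).

## Synthetic cohorts (`synthetic`)

The generator emulates, with a single integer seed driving derived
sub-streams:

* **Six planted cell phenotypes.** Each phenotype is a vector of signed
  offsets in standardised log2-intensity space over the 16-protein panel,
  encoding the qualitative profiles of the six clusters the analysis is
  designed to find (1: most proteins low; 2: XIAP/SMAC/CIAP1 high,
  procaspase-3 low — the "persister" profile; 3: all high; 4:
  procaspase-9 high, BAX/BAK low; 5: procaspase-3/BAX/BAK/APAF1 high,
  RIP3/FLIP low; 6: BID/RIP3/FLIP high). Offset vectors are scaled to a
  common Euclidean norm (contrast 2.5, giving per-marker offsets around
  ±1 SD). Equal contrast matters: raw ±1 encodings give profiles that
  mention many markers (1 and 3) several times the contrast of sparse
  profiles, a nested geometry that K-means-derived centroids on real data
  do not exhibit and that makes coarse merges spuriously stable.
* **Lognormal intensities with batch effects.** A cell's standardised
  vector is its phenotype centroid plus isotropic Gaussian noise
  (within-cluster SD 0.5), scaled to log2 intensities (mean 10, SD 1 per
  marker), shifted by a slide-level batch offset (SD 0.1 log2 units), and
  exponentiated. Within-cluster marker covariance is not modelled
  (independence assumption — a documented limitation; real co-regulation
  would correlate markers within a phenotype).
* **Compositions and outcomes.** Per-patient phenotype proportions are
  Dirichlet draws (concentration 0.8 per cluster and arm), which produce
  the dominant-cluster compositions seen across tumours. Recurrence times
  are exponential with hazard h0·exp(β2·p2 + β4·p4) in the treated arm
  only (defaults h0 = 0.008/month, β2 = log 3, β4 = −log 3), independent
  exponential censoring (0.005/month) and administrative censoring at a
  60-month follow-up horizon.
* **Scale.** Defaults mirror the study conditions: 194 patients (108
  treated, 86 surgery-only), 3000–6000 cells per patient over 2–3 cores,
  8 slides. Tests and examples run the same generator at reduced scale
  (tens of patients, tens of cells each — a few thousand cells) so that
  the full suite completes in minutes on one CPU; the planted-structure
  recovery properties being tested are scale-free at these sizes.
* A configurable contamination fraction plants QC-rule violations
  (cycling nuclei/area/alignment) to exercise the QC stage.

What passing tests on this generator do **not** show: robustness to
marker covariance within phenotypes, spatial autocorrelation of
phenotypes within cores, heavy-tailed or zero-inflated staining noise, or
misregistration artefacts beyond a scalar alignment score.

## Cohort-combining diagnostics (`balance`)

Pearson chi-square (no continuity correction) tests independence of each
categorical risk factor from treatment arm. If a T-stage level is
over-represented in one arm, `balance_by_downsampling` removes randomly
chosen patients with that level from the larger arm until counts are
equal (seed-reproducible; patients lacking the level are never removed).
Marker comparability across cohorts is tested per marker by histogramming
each slide's cell intensities on a common 64-bin grid spanning the pooled
0.5–99.5 percentile range (ε = 1e-12 added to empty bins), computing all
pairwise slide Jensen–Shannon divergences (base 2, so JSD ∈ [0, 1]),
comparing across-cohort with within-cohort pairs by a two-sided Wilcoxon
rank-sum test, and adjusting over markers by Benjamini–Hochberg.

## Phenotype discovery (`clustering`)

Per marker, extreme values are capped at the 1%/99% quantiles (linear
interpolation between order statistics) and columns standardised to zero
mean and unit population variance. K-means (best of `n_init`
k-means++ restarts, squared Euclidean distortion, deterministic under
seed) is fitted for k = 2…15. The number of phenotypes is selected by
consensus clustering: the same row subsets (default 100 subsamples of
50% of cells) are clustered at each k, pairwise co-assignment frequencies
are accumulated among co-sampled pairs, and PAC — the fraction of pair
consensus values strictly inside (0.1, 0.9) — is minimised over k (ties
to smaller k). Subsampling is the perturbation source, and its strength
matters: a gentle subsample (say 80% of rows) barely moves the K-means
solution, so at k one below the truth the single best merge of two
phenotypes is found identically every time and PAC fails to penalise it;
at 50% the merge choice must be re-made per subsample, which inflates
PAC below the true k while leaving it near zero at the truth. Each
subsample is clustered with multi-restart K-means (default 10 restarts)
so that local-minimum noise does not inflate PAC at the true k. Consensus
matrices are O(n²) and retained only for n ≤ 4000 cells by default; PAC
is always computed.

Markers are down-selected greedily by the Davies–Bouldin index (mean over
clusters of the worst (Si+Sj)/Mij ratio; lower = better separation): at
each step the marker whose removal most lowers DB is dropped if the
relative improvement is ≥ 1%, until no removal helps. This removes
pure-noise markers and may also drop weakly-contributing informative
markers — intended behaviour for a parsimony-driven selection.

Patient profiles are per-patient fractions over all clusters (cells
pooled across cores; absent clusters get 0; fractions sum to 1).

## Systems models of apoptosis competency (`models`)

Both models take per-cell molar concentrations and are integrated with a
stiff-capable adaptive solver (LSODA, rtol 1e-8, atol 1e-10), in μM and
minutes. All rate constants and references live in versioned YAML
parameter files, never in code. The named published models these follow
are not printed in full anywhere accessible, so the package defines
explicit minimal reaction schemes that reproduce every qualitative
behaviour the analysis relies on; rates were calibrated once against the
two anchors below and then frozen.

**MOMP sensitivity** (pore formation). A stress dose A (activator BH3
pool, default 0.2 μM ≙ 200 nM population mean) catalytically activates
pooled effector X = BAX+BAK → X*; A and X* are reversibly sequestered by
BCL2, BCL-XL and MCL-1 with species-specific affinities; 2X* → pore
irreversibly. Readout: maximum % of effector units in pores over 180 min
(attained at the horizon, pores being irreversible). Conserved moieties
(stress, effector units, each guardian) drift < 1e-6 relative. Pore % is
non-decreasing in dose/BAX/BAK and non-increasing in each guardian. The
minimal dose reaching 10% pores is found by geometric bracketing plus
bisection on [0, 10 μM] to relative tolerance 1e-3 (∞ if unreachable;
the bracketing step verifies monotonicity). Two sensitivity readings are
exposed: the study's default — sensitive iff required dose ≤ the
population mean of finite required doses (∞ cells are insensitive and
excluded from the mean) — and the alternative pore-fraction rule
(< 10% pores at the reference dose = low sensitivity). The "η" metric is
ambiguous in the source material (maximum pore % vs required dose); the
package computes both and defaults classification to the required-dose
reading, which is the one consistent with "low η ⇒ more sensitive".

**Caspase-3 activation** (execution downstream of MOMP). At t = 0 MOMP
has occurred: cytochrome c is non-limiting, so APAF1 → apoptosome;
apoptosome + procaspase-9 ⇌ active holoenzyme; holoenzyme cleaves
procaspase-3 → C3*; C3* feedback-cleaves procaspase-9 (weakly active free
caspase-9); XIAP reversibly inhibits C3* and the holoenzyme and mediates
C3* degradation (routed to an explicit sink so moiety totals stay
conserved); SMAC binds free XIAP and displaces it from its complexes;
C3* cleaves a reporter substrate. Readout: substrate cleavage % (SC%) at
60 min; SC% > 25 = high caspase activity (strict inequality at the
boundary). Cleavage onset is operationalised as cleaved substrate first
exceeding 1% of total (the source does not define it numerically); at
the reference concentration profile (APAF1 0.123 μM fixed — not limiting
for apoptosome formation in CRC — PC3 0.20, PC9 0.02, SMAC 0.40, XIAP
0.10 μM) the model holds ~10% of total SMAC in SMAC:XIAP complexes at
onset — the first calibration anchor, set via the SMAC-XIAP association
rate. The second anchor — an SC% distribution straddling the 25%
threshold on cohort-like concentration spreads, with the high-XIAP/
low-procaspase-3 phenotype lowest — is set by the XIAP-mediated
degradation and SMAC de-repression rates together with the width of the
reference quantile grids (log2-SD 2, the order-of-magnitude per-protein
spread of tumour cohorts). SC% is monotone decreasing in XIAP and
increasing in PC3/SMAC/PC9.

**Calibration.** MOMP inputs are linearly scaled through reference
cell-line anchors (`conc = intensity / ref_mean_intensity × ref_μM`);
caspase inputs are quantile-mapped (mid-rank empirical quantiles,
linearly interpolated into a reference μM quantile grid), so the cohort
median lands on the reference median. The shipped anchors and quantile
grids are synthetic calibration defaults (lognormal around the reference
medians, log2-SD 2) standing in for cell-line and cohort reference
measurements, which are inputs, not constants of the method.

## Survival analysis (`survival`)

Continuous patient-level features are dichotomised at the median with
ties assigned to "low" ("high" = strictly above the median). Per-arm
univariate Cox fits (one binary covariate each) are BH-adjusted across
features; multivariable fits add sex and age (dummy-coded categoricals,
collinear columns dropped with a warning) and report per-term HR/CI/p,
model likelihood-ratio p, partial AIC and concordance. Ties are handled
with Efron's partial likelihood (lifelines default; appropriate for
event times in months). Forward–backward stepwise selection uses Wald
p-values with entry/stay thresholds 0.15/0.15 (configurable;
deterministic given input order). Kaplan–Meier curves use the
product-limit estimator with a log-rank test for ≥ 2 groups. Cluster–
clinical associations use Spearman correlation (continuous) and
Kruskal–Wallis (categorical) with BH adjustment; arm-stratified analyses
never pool arms.

## Numerical choices and degenerate inputs

* Quantiles: linear interpolation between order statistics, everywhere.
* Standardisation uses population SD; constant columns raise (capping
  skips them with a log message).
* Empty clusters in K-means are relocated by the fitter to the points
  contributing most distortion, so fitted clusters are always non-empty.
* JSD of empty histograms, QC of empty tables, single-arm balance tests
  and single-cohort divergence tests raise informative errors.
* Bisection tolerances: required dose rel. 1e-3; ODE mass conservation
  checked to 1e-6 relative.
* High/low competency ratios with an empty denominator report ∞.

## Known limitations

* The ODE schemes are minimal: they reproduce the qualitative input–
  output behaviour (XIAP-limited execution, SMAC de-repression,
  guardian-stoichiometry MOMP threshold) but not the full mechanistic
  detail or published rate tables of the original models; absolute SC%
  and pore % values are calibration-dependent.
* The synthetic generator's independence and isotropy assumptions (see
  above) mean recovery results bound what the pipeline can do under
  idealised noise, not under real staining artefacts.
* PAC-based k selection inherits a known weakness: when phenotypes are
  both crisp and unevenly spaced, merging the closest pair can produce a
  consensus as stable as the true partition, so the PAC margin between
  the true k and k−1 can be thin.
* Cohort-specific published statistics (hazard ratios, AIC, concordance,
  cell counts) require the restricted patient data and are out of scope.
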