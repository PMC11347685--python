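"""Synthetic single-cell cohorts with planted apoptosis-cluster structure.

The generator emulates the statistical structure the analysis assumes, for a
stage II colorectal-cancer cohort imaged by multiplexed immunofluorescence:

* six cell phenotypes defined by signed marker offsets in standardised
  log2-intensity space (e.g. a "persister"-like phenotype with high XIAP,
  SMAC and CIAP1 but low procaspase-3, and a phenotype with high
  procaspase-9 and low BAX/BAK);
* lognormal marker intensities — cells are drawn around their phenotype
  centroid in standardised space, scaled to log2 intensities, shifted by a
  slide-level batch effect, and mapped to positive intensities by inverse
  log2;
* per-patient phenotype compositions drawn from a Dirichlet prior, so most
  patients have a dominant cluster;
* recurrence times from an exponential proportional-hazards model in which
  the hazard depends on the cluster-2 (and cluster-4) proportion in the
  chemotherapy-treated arm only.

Marker covariance within a cluster is not modelled (independent noise), and
cell positions are uniform within a core: spatial autocorrelation is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell_table import CellTable
from .panel import MarkerPanel, default_panel

#: Qualitative phenotype directions: +1 for "higher than average", -1 for
#: "lower", 0 (absent) for markers at the cohort average.
CLUSTER_DIRECTIONS: dict[int, dict[str, float]] = {
    # low expression of most proteins, average BAX/BAK
    1: {m: -1.0 for m in (
        "SMAC", "XIAP", "APAF1", "PC9", "PC3", "MCL1", "BCLXL", "BCL2",
        "FADD", "PC8", "FLIP", "RIP3", "CIAP1", "BID")},
    # high XIAP/SMAC/CIAP1, low procaspase-3: the caspase-inhibited profile
    2: {"XIAP": 1.0, "SMAC": 1.0, "CIAP1": 1.0, "PC3": -1.0},
    # uniformly high
    3: {m: 1.0 for m in (
        "SMAC", "XIAP", "APAF1", "PC9", "PC3", "MCL1", "BCLXL", "BCL2",
        "BAX", "BAK", "FADD", "PC8", "FLIP", "RIP3", "CIAP1", "BID")},
    # high procaspase-9, low BAX and BAK
    4: {"PC9": 1.0, "BAX": -1.0, "BAK": -1.0},
    # high procaspase-3/BAK/BAX/APAF1, low RIP3/FLIP
    5: {"PC3": 1.0, "BAK": 1.0, "BAX": 1.0, "APAF1": 1.0, "RIP3": -1.0, "FLIP": -1.0},
    # high BID/RIP3/FLIP: the death-receptor/necroptosis-primed profile
    6: {"BID": 1.0, "RIP3": 1.0, "FLIP": 1.0},
}


#: Per-phenotype contrast: each centroid's offset vector is scaled to this
#: Euclidean norm in standardised log2 space, so all six phenotypes carry a
#: comparable overall contrast (K-means centroids fitted to real data do not
#: favour phenotypes that merely mention more markers). Per-marker offsets
#: then land around +/-1 SD.
DEFAULT_CLUSTER_CONTRAST: float = 2.5


def scaled_offsets(directions: dict[int, dict[str, float]] | None = None,
                   contrast: float = DEFAULT_CLUSTER_CONTRAST) -> dict[int, dict[str, float]]:
    """Scale qualitative phenotype directions to a common contrast norm."""
    directions = directions or CLUSTER_DIRECTIONS
    out = {}
    for cid, offs in directions.items():
        norm = float(np.sqrt(sum(v * v for v in offs.values())))
        if norm == 0:
            raise ValueError(f"cluster {cid} has no marker offsets")
        out[cid] = {m: v * contrast / norm for m, v in offs.items()}
    return out


#: Default planted offsets: the qualitative directions at equal contrast.
CLUSTER_OFFSETS: dict[int, dict[str, float]] = scaled_offsets()


def centroid_matrix(panel: MarkerPanel | None = None,
                    offsets: dict[int, dict[str, float]] | None = None) -> np.ndarray:
    """Planted centroids as a (n_clusters, n_markers) array in panel order."""
    panel = panel or default_panel()
    offsets = offsets or CLUSTER_OFFSETS
    out = np.zeros((len(offsets), len(panel.names)))
    for row, cid in enumerate(sorted(offsets)):
        for m, v in offsets[cid].items():
            out[row, panel.names.index(m)] = v
    return out


@dataclass
class SyntheticConfig:
    """Cohort-generation settings.

    Defaults mirror the study conditions: 194 patients (108 adjuvant
    chemotherapy-treated, 86 surgery-only), 3000-6000 tumour cells per
    patient over 2-3 cores, 8 slides, six planted phenotypes, a 60-month
    follow-up horizon, and a treated-arm hazard increasing with the
    cluster-2 proportion and decreasing with the cluster-4 proportion.
    """

    n_patients: int = 194
    n_treated: int = 108
    cells_per_patient: tuple[int, int] = (3000, 6000)
    cores_per_patient: tuple[int, int] = (2, 3)
    n_slides: int = 8
    cluster_offsets: dict[int, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in CLUSTER_OFFSETS.items()})
    within_cluster_sd: float = 0.5
    batch_shift_sd: float = 0.1
    # Dirichlet concentrations per arm (treated, surgery); <1 total mass per
    # component yields the dominant-cluster compositions seen across tumours.
    composition_alpha_treated: tuple[float, ...] = (0.8,) * 6
    composition_alpha_surgery: tuple[float, ...] = (0.8,) * 6
    # log2-intensity scale per marker (lognormal base-2 intensities)
    log2_mean: float = 10.0
    log2_sd: float = 1.0
    # fraction of cells violating a QC rule (cycled over nuclei/area/alignment)
    qc_contamination: float = 0.0
    # survival model: h = h0 * exp(b2*p2*treated + b4*p4*treated), exponential
    baseline_hazard: float = 0.008          # events per month
    log_hr_cluster2: float = float(np.log(3.0))
    log_hr_cluster4: float = float(-np.log(3.0))
    censoring_hazard: float = 0.005         # independent exponential censoring
    followup_months: float = 60.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.within_cluster_sd < 0 or self.batch_shift_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.baseline_hazard <= 0 or self.censoring_hazard < 0:
            raise ValueError("hazard parameters must be non-negative (baseline > 0)")
        if not 0 <= self.qc_contamination <= 1:
            raise ValueError("qc_contamination must be in [0, 1]")
        if self.n_treated > self.n_patients:
            raise ValueError("n_treated exceeds n_patients")


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_cells(config: SyntheticConfig, panel: MarkerPanel | None = None
                   ) -> tuple[CellTable, dict]:
    """Generate a synthetic cell table with hidden true cluster labels.

    Returns the table and a truth record holding the per-cell true cluster
    (also carried in a ``true_cluster`` column), per-patient true phenotype
    proportions, treatment arms and the generating configuration seed.
    """
    panel = panel or default_panel()
    cluster_ids = sorted(config.cluster_offsets)
    centroids = centroid_matrix(panel, config.cluster_offsets)
    rng_comp, rng_cells, rng_batch, rng_qc = _rng_streams(config.rng_seed, 4)

    n_markers = len(panel.names)
    batch_shift = rng_batch.normal(0.0, config.batch_shift_sd,
                                   size=(config.n_slides, n_markers))

    alpha = {True: np.asarray(config.composition_alpha_treated, dtype=float),
             False: np.asarray(config.composition_alpha_surgery, dtype=float)}
    if any(len(a) != len(cluster_ids) for a in alpha.values()):
        raise ValueError("composition prior length must match number of clusters")

    lo, hi = config.cells_per_patient
    if hi <= 0:
        raise ValueError("zero cells requested")

    rows: list[pd.DataFrame] = []
    true_props: dict[str, np.ndarray] = {}
    arms: dict[str, bool] = {}
    cell_counter = 0
    for p in range(config.n_patients):
        pid = f"P{p + 1:04d}"
        treated = p < config.n_treated
        arms[pid] = treated
        slide = p % config.n_slides
        props = rng_comp.dirichlet(alpha[treated])
        true_props[pid] = props
        n_cells = int(rng_comp.integers(lo, hi + 1))
        n_cores = int(rng_comp.integers(config.cores_per_patient[0],
                                        config.cores_per_patient[1] + 1))
        labels = rng_cells.choice(cluster_ids, size=n_cells, p=props)
        z = centroids[np.searchsorted(cluster_ids, labels)] \
            + rng_cells.normal(0.0, config.within_cluster_sd, size=(n_cells, n_markers))
        log2_int = config.log2_mean + config.log2_sd * z + batch_shift[slide]
        intensity = np.exp2(log2_int)

        df = pd.DataFrame(intensity, columns=list(panel.names))
        df.insert(0, "cell_id", [f"C{cell_counter + i:08d}" for i in range(n_cells)])
        cell_counter += n_cells
        df.insert(1, "patient_id", pid)
        df.insert(2, "slide_id", f"S{slide + 1:02d}")
        df.insert(3, "core_id",
                  [f"{pid}_core{1 + (i % n_cores)}" for i in range(n_cells)])
        df.insert(4, "cohort", "A" if slide < config.n_slides // 2 else "B")
        df["x"] = rng_cells.uniform(0, 2000, size=n_cells)
        df["y"] = rng_cells.uniform(0, 2000, size=n_cells)
        df["n_nuclei"] = rng_cells.integers(1, 3, size=n_cells)
        for col in ("area_nucleus", "area_membrane", "area_cytoplasm"):
            df[col] = rng_cells.uniform(50, 800, size=n_cells)
        df["alignment_quality"] = rng_cells.uniform(0.90, 1.0, size=n_cells)
        df["true_cluster"] = labels
        rows.append(df)

    data = pd.concat(rows, ignore_index=True)

    if config.qc_contamination > 0:
        n = len(data)
        bad = rng_qc.random(n) < config.qc_contamination
        idx = np.flatnonzero(bad)
        rules = idx % 3  # cycle nuclei / area / alignment violations
        data.loc[idx[rules == 0], "n_nuclei"] = 3
        data.loc[idx[rules == 1], "area_membrane"] = 2000.0
        data.loc[idx[rules == 2], "alignment_quality"] = 0.5

    truth = {
        "true_cluster": data["true_cluster"].to_numpy(),
        "true_proportions": pd.DataFrame(
            true_props, index=[f"cluster_{c}" for c in cluster_ids]).T,
        "treated": arms,
        "rng_seed": config.rng_seed,
    }
    return CellTable(data=data, panel=panel), truth


def simulate_survival(proportions: pd.DataFrame, treated: dict[str, bool] | pd.Series,
                      config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Draw recurrence outcomes for patients given phenotype proportions.

    ``proportions`` is indexed by patient_id with columns ``cluster_<i>``.
    The event hazard is ``h0 * exp(b2 * p2 * treated + b4 * p4 * treated)``
    with independent exponential censoring and administrative censoring at
    the follow-up horizon. Returns a clinical table with demographics drawn
    from cohort-typical distributions.
    """
    rng = np.random.default_rng(config.rng_seed + 1 if seed is None else seed)
    treated = pd.Series(treated)
    pids = list(proportions.index)
    p2 = proportions.get("cluster_2", pd.Series(0.0, index=proportions.index))
    p4 = proportions.get("cluster_4", pd.Series(0.0, index=proportions.index))
    arm = treated.loc[pids].astype(float).to_numpy()
    hazard = config.baseline_hazard * np.exp(
        config.log_hr_cluster2 * p2.to_numpy() * arm
        + config.log_hr_cluster4 * p4.to_numpy() * arm)
    event_time = rng.exponential(1.0 / hazard)
    if config.censoring_hazard > 0:
        censor_time = rng.exponential(1.0 / config.censoring_hazard, size=len(pids))
    else:
        censor_time = np.full(len(pids), np.inf)
    censor_time = np.minimum(censor_time, config.followup_months)
    time = np.minimum(event_time, censor_time)
    event = event_time <= censor_time

    return pd.DataFrame({
        "patient_id": pids,
        "age": np.round(rng.normal(68, 10, size=len(pids))).clip(30, 95),
        "sex": rng.choice(["F", "M"], size=len(pids)),
        "location": rng.choice(["left", "right", "rectum"], size=len(pids), p=[0.45, 0.4, 0.15]),
        "t_stage": rng.choice(["T3", "T4"], size=len(pids), p=[0.85, 0.15]),
        "grade": rng.choice(["well/moderate", "poor"], size=len(pids), p=[0.9, 0.1]),
        "treated": treated.loc[pids].to_numpy(),
        "time": np.maximum(time, 1e-3),
        "event": event,
    })


def simulate_cohort(config: SyntheticConfig, panel: MarkerPanel | None = None
                    ) -> tuple[CellTable, pd.DataFrame, dict]:
    """Cells plus matched clinical outcomes in one call."""
    cells, truth = simulate_cells(config, panel)
    clinical = simulate_survival(truth["true_proportions"], truth["treated"], config)
    return cells, clinical, truth
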