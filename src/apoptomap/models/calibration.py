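"""Intensity-to-molar calibration for the ODE model inputs.

Imaging intensities are in arbitrary units; the models need uM. Two
alignment strategies are used, one per model:

* **linear** (MOMP inputs BAX/BAK/BCL2/BCL-XL/MCL-1): intensities are
  scaled by reference cell-line anchors measured alongside the cohort —
  ``conc = intensity / ref_mean_intensity * ref_uM`` — so a cell at the
  reference mean intensity gets exactly the reference concentration.
* **quantile** (caspase inputs PC3/PC9/SMAC/XIAP): each marker's cohort
  intensity distribution is mapped monotonically onto a reference molar
  distribution given as a quantile grid, so the cohort median lands on the
  reference median.

APAF1 is not limiting for apoptosome formation in this setting and is fixed
at its reference median (0.123 uM) rather than calibrated per cell.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..panel import CASPASE_INPUT_MARKERS, MOMP_INPUT_MARKERS

APAF1_FIXED_UM = 0.123


def linear_calibration(intensities: pd.DataFrame, anchors: dict) -> pd.DataFrame:
    """Scale intensities through per-marker reference anchors.

    ``anchors[marker] = {"mean_intensity": ..., "uM": ...}``. Output columns
    are lowercased marker names.
    """
    out = {}
    for m in intensities.columns:
        if m not in anchors:
            raise KeyError(f"no linear calibration anchor for marker {m}")
        a = anchors[m]
        out[m.lower()] = intensities[m].to_numpy(float) / a["mean_intensity"] * a["uM"]
    res = pd.DataFrame(out, index=intensities.index)
    if (res.to_numpy() < 0).any():
        raise ValueError("negative concentration after linear calibration")
    return res


def quantile_calibration(intensities: pd.DataFrame, reference: dict) -> pd.DataFrame:
    """Monotone quantile map of cohort intensities onto reference uM grids.

    ``reference[marker] = {"probs": [...], "quantiles_uM": [...]}``. Each
    cell's empirical quantile rank (mid-rank convention, ties averaged) is
    interpolated into the reference quantile function, so a cell at the
    cohort median receives the reference median concentration.
    """
    out = {}
    for m in intensities.columns:
        if m not in reference:
            raise KeyError(f"no quantile reference for marker {m}")
        probs = np.asarray(reference[m]["probs"], dtype=float)
        quants = np.asarray(reference[m]["quantiles_uM"], dtype=float)
        if not (np.all(np.diff(probs) > 0) and np.all(np.diff(quants) >= 0)):
            raise ValueError(f"reference quantile grid for {m} must be increasing")
        x = intensities[m].to_numpy(float)
        n = x.size
        ranks = pd.Series(x).rank(method="average").to_numpy()
        p = (ranks - 0.5) / n
        out[m.lower()] = np.interp(p, probs, quants)
    return pd.DataFrame(out, index=intensities.index)


def calibrate_intensity_to_molar(table, reference: dict,
                                 apaf1_uM: float | None = None) -> pd.DataFrame:
    """Build the per-cell uM input frame for both ODE models.

    ``reference`` carries ``momp_reference`` (linear anchors) and
    ``caspase_reference`` (quantile grids); see the default parameter files.
    Returns a DataFrame indexed by cell_id with lowercase columns
    bax/bak/bcl2/bclxl/mcl1/pc3/pc9/smac/xiap/apaf1.
    """
    df = table.data.set_index("cell_id")
    momp = linear_calibration(df[list(MOMP_INPUT_MARKERS)], reference["momp_reference"])
    casp_markers = [m for m in CASPASE_INPUT_MARKERS if m != "APAF1"]
    casp = quantile_calibration(df[casp_markers], reference["caspase_reference"])
    conc = pd.concat([momp, casp], axis=1)
    conc["apaf1"] = APAF1_FIXED_UM if apaf1_uM is None else apaf1_uM
    return conc
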