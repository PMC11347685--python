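"""Loading of versioned model parameter files.

All rate constants, reference concentrations and calibration anchors live
in YAML files shipped with the package (``models/params/``), never
hard-coded, so a re-parameterisation is a data change. Each file records
units and a provenance comment per block.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .caspase import CaspaseParams
from .momp import MompParams


def _load_yaml(name: str, path=None) -> dict:
    if path is not None:
        return yaml.safe_load(Path(path).read_text())
    ref = resources.files("apoptomap.models") / "params" / name
    return yaml.safe_load(ref.read_text())


def load_momp_params(path=None) -> tuple[MompParams, dict]:
    """Default (or custom) MOMP model parameters and calibration reference.

    Returns ``(MompParams, reference)`` where ``reference["momp_reference"]``
    holds the linear intensity->uM anchors.
    """
    raw = _load_yaml("momp_default.yaml", path)
    r = raw["rates"]
    params = MompParams(
        stress_dose=raw["stress_dose"],
        k_act=r["k_act"],
        k_pore=r["k_pore"],
        binding={s: (b["kf_stress"], b["kr_stress"], b["kf_effector"], b["kr_effector"])
                 for s, b in r["binding"].items()},
        horizon=raw["horizon"],
        pore_threshold_pct=raw["pore_threshold_pct"],
    )
    reference = {"momp_reference": raw["reference_anchors"],
                 "reference_concentrations_uM": raw["reference_concentrations_uM"]}
    return params, reference


def load_caspase_params(path=None) -> tuple[CaspaseParams, dict]:
    """Default (or custom) caspase model parameters and references.

    Returns ``(CaspaseParams, reference)`` where the reference dict holds
    the quantile calibration grids and the reference concentration profile
    used as the calibration anchor.
    """
    raw = _load_yaml("caspase_default.yaml", path)
    params = CaspaseParams(**raw["rates"],
                           substrate_total=raw["substrate_total"],
                           horizon=raw["horizon"],
                           sc_threshold_pct=raw["sc_threshold_pct"],
                           onset_frac=raw["onset_frac"])
    reference = {"caspase_reference": raw["reference_quantiles"],
                 "reference_concentrations_uM": raw["reference_concentrations_uM"]}
    return params, reference


def load_reference(momp_path=None, caspase_path=None) -> dict:
    """Combined calibration reference for ``calibrate_intensity_to_molar``."""
    _, momp_ref = load_momp_params(momp_path)
    _, casp_ref = load_caspase_params(caspase_path)
    return {"momp_reference": momp_ref["momp_reference"],
            "caspase_reference": casp_ref["caspase_reference"]}
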