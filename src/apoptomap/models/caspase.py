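"""Minimal ODE model of caspase-3 activation downstream of MOMP.

The model starts at the moment of MOMP: cytochrome c is non-limiting, so
APAF1 converts to apoptosome scaffolds; apoptosome recruits procaspase-9
into an active holoenzyme; the holoenzyme cleaves procaspase-3 into active
caspase-3, which feedback-cleaves procaspase-9 (yielding a weaker, free
active caspase-9) and cleaves a reporter substrate. XIAP reversibly
inhibits both caspase-3 and the holoenzyme and mediates caspase-3
degradation; SMAC (released at MOMP) neutralises XIAP by binding free XIAP
and displacing it from its complexes.

The readout is the substrate-cleavage percentage (SC%) at the horizon
(default 60 min): cells with SC% > 25 execute apoptosis, cells at or below
25% have inhibited effector caspase activity and can survive MOMP
("persister" behaviour, typically high XIAP with low procaspase-3). The
model also reports the fraction of total SMAC sequestered by XIAP at the
onset of substrate cleavage (first time cleaved substrate exceeds 1% of
total) — a small fraction (about 10%), reflecting that SMAC acts mostly
after cleavage has begun. Units are uM and minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp


@dataclass
class CaspaseParams:
    """Rate constants (1/(uM*min) for bimolecular, 1/min otherwise)."""

    k_apop: float = 0.5        # APAF1 -> apoptosome (cytochrome c non-limiting)
    k_holo_f: float = 10.0     # apoptosome + PC9 -> holoenzyme
    k_holo_r: float = 0.5
    k_c3_cleave: float = 30.0  # holoenzyme cleaves PC3 -> C3
    k_c3_by_c9c: float = 1.0   # cleaved free caspase-9 cleaves PC3 (weak)
    k_fb: float = 5.0          # C3 feedback-cleaves PC9 -> C9c
    k_x_c3_f: float = 50.0     # XIAP binds C3
    k_x_c3_r: float = 0.1
    k_x_holo_f: float = 20.0   # XIAP binds holoenzyme
    k_x_holo_r: float = 0.1
    k_smac_f: float = 1.0      # SMAC binds free XIAP
    k_smac_r: float = 0.02
    k_derepress_c3: float = 2.0    # SMAC + XIAP:C3 -> SMAC:XIAP + C3
    k_derepress_holo: float = 2.0  # SMAC + XIAP:holo -> SMAC:XIAP + holo
    k_deg: float = 0.5         # XIAP:C3 -> XIAP (C3 degradation)
    k_sub: float = 10.0        # C3 cleaves substrate
    substrate_total: float = 1.0   # reporter substrate, uM
    horizon: float = 60.0      # minutes
    sc_threshold_pct: float = 25.0
    onset_frac: float = 0.01   # cleavage onset: cSub exceeds this fraction
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        for name, v in self.__dict__.items():
            if name.startswith("k_") and v < 0:
                raise ValueError(f"negative rate constant {name}")


@dataclass
class CaspaseResult:
    """Per-cell caspase-activation readouts."""

    cell_id: str
    sc_pct: float
    smac_bound_frac_at_onset: float  # NaN if onset never reached
    high_activity: bool | None = None


# state: [Apaf, Apop, PC9, Holo, PC3, C3, XIAP, XC3, XHolo, SMAC, SX,
#         Sub, cSub, C3deg, C9c]
_IDX = {n: i for i, n in enumerate(
    ("apaf", "apop", "pc9", "holo", "pc3", "c3", "xiap", "xc3", "xholo",
     "smac", "sx", "sub", "csub", "c3deg", "c9c"))}


def _rhs(t, y, p: CaspaseParams):
    apaf, apop, pc9, holo, pc3, c3, xiap, xc3, xholo, smac, sx, sub, csub, c3deg, c9c = y
    r1 = p.k_apop * apaf
    r2f = p.k_holo_f * apop * pc9
    r2r = p.k_holo_r * holo
    r3 = p.k_c3_cleave * holo * pc3
    r3b = p.k_c3_by_c9c * c9c * pc3
    r4 = p.k_fb * c3 * pc9
    r5f = p.k_x_c3_f * xiap * c3
    r5r = p.k_x_c3_r * xc3
    r6f = p.k_x_holo_f * xiap * holo
    r6r = p.k_x_holo_r * xholo
    r7f = p.k_smac_f * smac * xiap
    r7r = p.k_smac_r * sx
    r8 = p.k_derepress_c3 * smac * xc3
    r8b = p.k_derepress_holo * smac * xholo
    r9 = p.k_deg * xc3
    r10 = p.k_sub * c3 * sub
    dy = np.empty(15)
    dy[0] = -r1
    dy[1] = r1 - r2f + r2r
    dy[2] = -r2f + r2r - r4
    dy[3] = r2f - r2r - r6f + r6r + r8b
    dy[4] = -r3 - r3b
    dy[5] = r3 + r3b - r5f + r5r + r8
    dy[6] = -r5f + r5r - r6f + r6r - r7f + r7r + r9
    dy[7] = r5f - r5r - r8 - r9
    dy[8] = r6f - r6r - r8b
    dy[9] = -r7f + r7r - r8 - r8b
    dy[10] = r7f - r7r + r8 + r8b
    dy[11] = -r10
    dy[12] = r10
    dy[13] = r9
    dy[14] = r4
    return dy


def simulate_apopto_cell(conc, params: CaspaseParams | None = None,
                         cell_id: str = "", n_eval: int = 0):
    """Integrate the caspase-activation model for one cell.

    ``conc`` maps lowercase protein names to uM: apaf1, pc3, pc9, smac,
    xiap. Returns ``(result, trajectory)``; ``result.sc_pct`` is the
    substrate-cleavage percentage at the horizon and
    ``result.smac_bound_frac_at_onset`` the fraction of total SMAC held in
    SMAC:XIAP complexes when cleaved substrate first exceeds 1% of total
    (NaN if it never does). All moieties are conserved (the XIAP-mediated
    caspase-3 degradation flux is routed to an explicit sink, so the
    caspase-3 moiety total includes it).
    """
    p = params or CaspaseParams()
    y0 = np.zeros(15)
    y0[_IDX["apaf"]] = float(conc["apaf1"])
    y0[_IDX["pc9"]] = float(conc["pc9"])
    y0[_IDX["pc3"]] = float(conc["pc3"])
    y0[_IDX["xiap"]] = float(conc["xiap"])
    y0[_IDX["smac"]] = float(conc["smac"])
    y0[_IDX["sub"]] = p.substrate_total
    if (y0 < 0).any():
        raise ValueError(f"negative concentration for cell {cell_id!r}")

    onset_level = p.onset_frac * p.substrate_total

    def onset(t, y, _p):
        return y[_IDX["csub"]] - onset_level
    onset.direction = 1.0

    t_eval = np.linspace(0.0, p.horizon, n_eval) if n_eval else None
    sol = solve_ivp(_rhs, (0.0, p.horizon), y0, method="LSODA", args=(p,),
                    rtol=p.rtol, atol=p.atol, events=onset, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"caspase integration failed for cell {cell_id!r}: {sol.message}")

    sc_pct = 100.0 * sol.y[_IDX["csub"], -1] / p.substrate_total
    smac_total = y0[_IDX["smac"]]
    if sol.y_events[0].shape[0] and smac_total > 0:
        y_on = sol.y_events[0][0]
        bound = float(y_on[_IDX["sx"]]) / smac_total
        t_onset = float(sol.t_events[0][0])
    else:
        bound, t_onset = float("nan"), float("nan")
    result = CaspaseResult(cell_id=cell_id, sc_pct=float(sc_pct),
                           smac_bound_frac_at_onset=bound,
                           high_activity=bool(sc_pct > p.sc_threshold_pct))
    traj = {"t": sol.t, "y": sol.y, "t_onset": t_onset, "species_index": dict(_IDX)}
    return result, traj


def conserved_moieties(y: np.ndarray) -> dict[str, np.ndarray]:
    """Time courses of moiety totals (degradation routed to its sink)."""
    i = _IDX
    return {
        "apaf1": y[i["apaf"]] + y[i["apop"]] + y[i["holo"]] + y[i["xholo"]],
        "caspase9": y[i["pc9"]] + y[i["holo"]] + y[i["xholo"]] + y[i["c9c"]],
        "caspase3": y[i["pc3"]] + y[i["c3"]] + y[i["xc3"]] + y[i["c3deg"]],
        "xiap": y[i["xiap"]] + y[i["xc3"]] + y[i["xholo"]] + y[i["sx"]],
        "smac": y[i["smac"]] + y[i["sx"]],
        "substrate": y[i["sub"]] + y[i["csub"]],
    }


def classify_caspase(sc_pct, threshold_pct: float = 25.0) -> np.ndarray:
    """High caspase-3 activity iff SC% strictly exceeds the threshold."""
    return np.asarray(sc_pct, dtype=float) > threshold_pct
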