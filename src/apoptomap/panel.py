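"""Marker panel definitions for the apoptosis-pathway protein set.

The panel covers 16 proteins of the intrinsic (mitochondrial) and extrinsic
(death-receptor) apoptosis pathways as measured by multiplexed
immunofluorescence. Procaspase-3 and XIAP sit at the convergence point of the
two pathways and belong to both sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical marker identifiers, in panel order.
INTRINSIC_MARKERS: tuple[str, ...] = (
    "SMAC", "XIAP", "APAF1", "PC9", "PC3",
    "MCL1", "BCLXL", "BCL2", "BAX", "BAK",
)
EXTRINSIC_MARKERS: tuple[str, ...] = (
    "FADD", "PC3", "PC8", "FLIP", "RIP3", "XIAP", "CIAP1", "BID",
)

#: Inputs of the MOMP-sensitivity model (BCL2-family stoichiometry).
MOMP_INPUT_MARKERS: tuple[str, ...] = ("BAX", "BAK", "BCL2", "BCLXL", "MCL1")
#: Inputs of the caspase-activation model (apoptosome / XIAP / SMAC axis).
CASPASE_INPUT_MARKERS: tuple[str, ...] = ("APAF1", "PC3", "PC9", "SMAC", "XIAP")


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered set of markers with pathway membership.

    Parameters
    ----------
    names
        Ordered, duplicate-free marker identifiers.
    pathway
        Map from marker to ``"intrinsic"``, ``"extrinsic"`` or ``"both"``.
    """

    names: tuple[str, ...]
    pathway: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate markers in panel")
        unknown = set(self.pathway) - set(self.names)
        if unknown:
            raise ValueError(f"pathway assignment for unknown markers: {sorted(unknown)}")

    @property
    def intrinsic(self) -> tuple[str, ...]:
        return tuple(m for m in self.names if self.pathway.get(m) in ("intrinsic", "both"))

    @property
    def extrinsic(self) -> tuple[str, ...]:
        return tuple(m for m in self.names if self.pathway.get(m) in ("extrinsic", "both"))

    def subset(self, which: str) -> tuple[str, ...]:
        """Markers for a clustering run: ``integrated``, ``intrinsic`` or ``extrinsic``."""
        if which == "integrated":
            return self.names
        if which == "intrinsic":
            return self.intrinsic
        if which == "extrinsic":
            return self.extrinsic
        raise ValueError(f"unknown pathway subset {which!r}")


def default_panel() -> MarkerPanel:
    """The 16-protein apoptosis panel with pathway membership."""
    names = tuple(dict.fromkeys(INTRINSIC_MARKERS + EXTRINSIC_MARKERS))
    intrinsic = set(INTRINSIC_MARKERS)
    extrinsic = set(EXTRINSIC_MARKERS)
    pathway = {
        m: ("both" if m in intrinsic and m in extrinsic
            else "intrinsic" if m in intrinsic else "extrinsic")
        for m in names
    }
    return MarkerPanel(names=names, pathway=pathway)
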