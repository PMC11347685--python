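"""Single-cell intensity tables: I/O, quality control and normalisation.

The pipeline starts from a segmented-cell table (one row per cell) carrying
identifiers, spatial position, compartment areas, a per-round alignment
quality score and per-marker mean intensities in arbitrary units. Epithelial
versus stromal assignment is an upstream segmentation output and arrives as
an input column; no pixel-level processing happens here.

Quality control keeps cells with 1-2 nuclei, every subcellular compartment
area strictly between the configured pixel bounds, and staining-round
alignment at or above a cohort-specific minimum (0.80 or 0.85 depending on
the cohort). Intensities are then log2-transformed (with a pseudocount, to
keep zero intensities defined) and slide batch effects removed by
median-centring each slide per marker in log2 space, preserving the global
per-marker median.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import MarkerPanel, default_panel

logger = logging.getLogger(__name__)

#: Columns every cell table must provide, besides one column per panel marker.
REQUIRED_COLUMNS: tuple[str, ...] = (
    "cell_id", "patient_id", "slide_id", "core_id",
    "n_nuclei", "area_nucleus", "area_membrane", "area_cytoplasm",
    "alignment_quality",
)
#: Optional columns filled with a sentinel when absent.
OPTIONAL_COLUMNS: dict[str, object] = {"cohort": "NA", "x": np.nan, "y": np.nan}

AREA_COLUMNS = ("area_nucleus", "area_membrane", "area_cytoplasm")

CLINICAL_REQUIRED = ("patient_id", "age", "sex", "t_stage", "treated", "time", "event")
CLINICAL_OPTIONAL: dict[str, object] = {
    "location": "NA", "grade": "NA", "mmr": "NA", "lvi": "NA", "recurrence_site": "NA",
}


class SchemaError(ValueError):
    """A required column or marker is missing from an input table."""


@dataclass
class CellTable:
    """A segmented-cell intensity table plus its marker panel.

    ``data`` holds one row per cell; marker intensities live in columns named
    after the panel markers.
    """

    data: pd.DataFrame
    panel: MarkerPanel
    log2_transformed: bool = False

    def __len__(self) -> int:
        return len(self.data)

    @property
    def markers(self) -> tuple[str, ...]:
        return self.panel.names

    def intensities(self, markers=None) -> pd.DataFrame:
        """Intensity sub-frame in panel order (or a given marker order)."""
        return self.data[list(markers or self.panel.names)]

    def copy(self) -> "CellTable":
        return replace(self, data=self.data.copy())


@dataclass(frozen=True)
class QcConfig:
    """Cell-level quality-control thresholds.

    Areas are in pixels and compared with strict inequalities
    (``area_min < area < area_max``); alignment_quality is the per-round
    correlation with the first staining round, in [0, 1].
    """

    nuclei_min: int = 1
    nuclei_max: int = 2
    area_min: float = 10.0
    area_max: float = 1500.0
    alignment_min: float = 0.80

    def __post_init__(self) -> None:
        if not self.area_min < self.area_max:
            raise ValueError("area_min must be < area_max")
        if self.nuclei_min > self.nuclei_max:
            raise ValueError("nuclei_min must be <= nuclei_max")
        if not 0.0 <= self.alignment_min <= 1.0:
            raise ValueError("alignment_min must be in [0, 1]")


@dataclass
class QcReport:
    """Removal counts attributed to the first failing rule, in rule order."""

    n_input: int
    n_kept: int
    removed: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps({"n_input": self.n_input, "n_kept": self.n_kept, **self.removed})


def read_cell_table(path, panel: MarkerPanel | None = None) -> CellTable:
    """Read a comma-delimited single-cell table and validate its schema.

    Raises
    ------
    SchemaError
        If a required column or a panel marker column is absent.
    ValueError
        If an intensity value fails to parse as a number (the offending row
        index is reported).
    """
    panel = panel or default_panel()
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in (*REQUIRED_COLUMNS, *panel.names) if c not in df.columns]
    if missing:
        raise SchemaError(f"cell table {path} is missing required column(s): {missing}")
    for col, sentinel in OPTIONAL_COLUMNS.items():
        if col not in df.columns:
            df[col] = sentinel
    for m in panel.names:
        try:
            df[m] = pd.to_numeric(df[m], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[m], errors="coerce").isna() & df[m].notna()]
            row = int(bad[0]) if len(bad) else -1
            raise ValueError(f"non-numeric intensity for {m} at row {row}") from exc
        if (df[m] < 0).any():
            raise ValueError(f"negative intensity for marker {m}")
    return CellTable(data=df, panel=panel)


def write_cell_table(table: CellTable, path) -> None:
    """Write a cell table as comma-delimited text (UTF-8, header row)."""
    table.data.to_csv(path, index=False)


def read_clinical_table(path) -> pd.DataFrame:
    """Read a per-patient clinical table (one row per patient)."""
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"clinical table is missing required column(s): {missing}")
    if df["patient_id"].duplicated().any():
        raise ValueError("clinical table has duplicate patient_id rows")
    if (df["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    for col, sentinel in CLINICAL_OPTIONAL.items():
        if col not in df.columns:
            df[col] = sentinel
    return df


def apply_qc_filters(table: CellTable, qc: QcConfig | None = None) -> tuple[CellTable, QcReport]:
    """Apply cell-level QC and report removals per first-failing rule.

    A cell is kept iff its nuclei count is within [nuclei_min, nuclei_max],
    every compartment area is strictly inside (area_min, area_max), and its
    alignment quality is >= alignment_min. Cells failing several rules are
    counted once, under the first failing rule in the order
    nuclei -> area -> alignment; removal itself does not depend on the order.
    """
    if len(table) == 0:
        raise ValueError("cannot QC an empty cell table")
    qc = qc or QcConfig()
    df = table.data

    nuclei_ok = df["n_nuclei"].between(qc.nuclei_min, qc.nuclei_max)
    area_ok = np.ones(len(df), dtype=bool)
    for col in AREA_COLUMNS:
        area_ok &= (df[col] > qc.area_min) & (df[col] < qc.area_max)
    align_ok = df["alignment_quality"] >= qc.alignment_min

    keep = nuclei_ok & area_ok & align_ok
    fail_nuclei = ~nuclei_ok
    fail_area = nuclei_ok & ~area_ok
    fail_align = nuclei_ok & area_ok & ~align_ok
    report = QcReport(
        n_input=len(df),
        n_kept=int(keep.sum()),
        removed={
            "nuclei": int(fail_nuclei.sum()),
            "area": int(fail_area.sum()),
            "alignment": int(fail_align.sum()),
        },
    )
    out = replace(table, data=df.loc[keep].reset_index(drop=True))
    return out, report


def log2_transform(table: CellTable, pseudocount: float = 1.0) -> CellTable:
    """log2(intensity + pseudocount) per marker; order-preserving.

    The pseudocount (default 1.0) keeps zero intensities defined and maps
    them to exactly 0.
    """
    df = table.data.copy()
    vals = df[list(table.markers)].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative intensities: log2 transform undefined")
    df[list(table.markers)] = np.log2(vals + pseudocount)
    return replace(table, data=df, log2_transformed=True)


def normalize_slides(table: CellTable, method: str = "median") -> CellTable:
    """Remove slide-level batch effects by per-marker median centring.

    For each slide and marker (in log2 space), subtract the slide median and
    add the global marker median, so the global per-marker median is
    unchanged and within-slide ordering is preserved. Slides with fewer than
    two cells are passed through unshifted (with a warning).
    """
    if method != "median":
        raise ValueError(f"unknown normalisation method {method!r}")
    if not table.log2_transformed:
        logger.warning("normalize_slides called on a table not marked log2-transformed")
    df = table.data.copy()
    markers = list(table.markers)
    global_med = df[markers].median()
    for slide, idx in df.groupby("slide_id").groups.items():
        if len(idx) < 2:
            logger.warning("slide %s has <2 cells; passed through unshifted", slide)
            continue
        block = df.loc[idx, markers]
        df.loc[idx, markers] = block - block.median() + global_med
    return replace(table, data=df)


def patient_marker_means(table: CellTable) -> pd.DataFrame:
    """Per-patient mean marker intensity, pooling all cells across cores.

    Returns a DataFrame indexed by patient_id with one column per marker.
    Patients contributing zero cells simply do not appear (logged upstream
    by the caller if needed).
    """
    return table.data.groupby("patient_id")[list(table.markers)].mean()
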