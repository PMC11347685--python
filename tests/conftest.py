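"""Shared fixtures: small synthetic cohorts and hand-built toy tables."""

import numpy as np
import pandas as pd
import pytest

from apoptomap.cell_table import CellTable
from apoptomap.panel import default_panel
from apoptomap.synthetic import SyntheticConfig, simulate_cells


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort():
    """~2000 cells, 40 patients, default planted structure (seed 7)."""
    cfg = SyntheticConfig(n_patients=40, n_treated=20, cells_per_patient=(40, 60),
                          rng_seed=7)
    cells, truth = simulate_cells(cfg)
    return cells, truth, cfg


def make_toy_table(panel, rows: int = 5) -> CellTable:
    """A tiny well-formed cell table with constant intensity 100."""
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(rows)],
        "patient_id": ["p1"] * rows,
        "slide_id": ["s1"] * rows,
        "core_id": ["p1_core1"] * rows,
        "cohort": ["A"] * rows,
        "x": rng.uniform(0, 100, rows),
        "y": rng.uniform(0, 100, rows),
        "n_nuclei": [1] * rows,
        "area_nucleus": [100.0] * rows,
        "area_membrane": [200.0] * rows,
        "area_cytoplasm": [300.0] * rows,
        "alignment_quality": [0.95] * rows,
    })
    for m in panel.names:
        df[m] = 100.0
    return CellTable(data=df, panel=panel)


@pytest.fixture
def toy_table(panel):
    return make_toy_table(panel)


@pytest.fixture
def qc_toy_table(panel):
    """Five cells: one bad nuclei count, one oversized membrane, one poor
    alignment, two clean."""
    t = make_toy_table(panel, rows=5)
    t.data.loc[0, "n_nuclei"] = 3
    t.data.loc[1, "area_membrane"] = 2000.0
    t.data.loc[2, "alignment_quality"] = 0.70
    return t
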