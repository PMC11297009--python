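"""Shared fixtures: programmatic construction of tiny phenotyped cores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spatsig.cell_data import CoreWindow, PANEL_MARKERS

# which marker columns a generator-level phenotype label switches on
_LABEL_MARKERS = {
    "Tumor": {"CK"},
    "CD4Treg": {"CD4", "FOXP3"},
    "CD4Tcon": {"CD4"},
    "CD8Treg": {"CD8", "FOXP3"},
    "CD8Tcon": {"CD8"},
    "FOXP3pos": {"FOXP3"},
    "PD1pos": {"PD1"},
    "PDL1pos": {"PDL1"},
    "other": set(),            # CD4+CD8+ double positive, gated to no lineage
    "double": {"CD4", "CD8"},
}


def make_core(points_by_phen: dict[str, list[tuple[float, float]]],
              panel: str = "panel1", region: str = "IM",
              core_id: str = "C1", patient_id: str = "P1",
              width_um: float = 1000.0, height_um: float = 1000.0) -> CoreWindow:
    """Build a CoreWindow from {phenotype label: [(x, y), ...]}."""
    markers = PANEL_MARKERS[panel]
    rows = []
    for label, pts in points_by_phen.items():
        on = _LABEL_MARKERS[label]
        for x, y in pts:
            rows.append({"x_um": float(x), "y_um": float(y),
                         **{m: int(m in on) for m in markers}})
    df = pd.DataFrame(rows)
    if len(df):
        df.insert(0, "cell_id", [f"{core_id}-{i}" for i in range(len(df))])
    return CoreWindow(core_id=core_id, patient_id=patient_id, region=region,
                      panel=panel, width_um=width_um, height_um=height_um,
                      cells=df)


def random_core(rng: np.random.Generator, n_cells: int = 200,
                panel: str = "panel1", region: str = "IM",
                core_id: str = "R1", patient_id: str = "P1",
                width_um: float = 1000.0, height_um: float = 1000.0) -> CoreWindow:
    """Core with uniform coordinates and independent random marker calls."""
    markers = PANEL_MARKERS[panel]
    df = pd.DataFrame({
        "cell_id": [f"{core_id}-{i}" for i in range(n_cells)],
        "x_um": rng.uniform(0, width_um, n_cells),
        "y_um": rng.uniform(0, height_um, n_cells),
    })
    for m in markers:
        df[m] = rng.integers(0, 2, n_cells)
    return CoreWindow(core_id=core_id, patient_id=patient_id, region=region,
                      panel=panel, width_um=width_um, height_um=height_um,
                      cells=df)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240802)
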