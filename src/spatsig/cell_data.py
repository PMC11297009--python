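"""Cell and patient tables for multiplex-immunofluorescence (mIF) spatial analysis.

A tissue-microarray (TMA) experiment yields, per patient, small tissue cores
from two regions — the invasive margin (IM) and the tumor center (TC) — each
scanned and segmented into a per-cell table: 2-D coordinates in micrometres
plus boolean marker positivity calls.  Two staining panels are supported:

* ``panel1`` — CK (cytokeratin, epithelial/tumor), CD4, CD8, FOXP3;
* ``panel2`` — CK, FOXP3, PD1, PDL1.

Phenotype gating follows a fixed hierarchy: CK positivity dominates (the cell
is a tumor cell and is excluded from every T-cell gate); within the CK−
compartment CD4 and CD8 lineages are mutually exclusive, and cells positive
for both are assigned to neither ("other").  FOXP3 then splits each lineage
into regulatory (Treg) and conventional (Tcon) subsets.  ``CD4all`` /
``CD8all`` denote the whole lineage (Treg ∪ Tcon).  Checkpoint gates
(``PD1pos``, ``PDL1pos``) are purely marker-based because PD-L1 is expressed
on tumor cells as well as immune cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGIONS = ("IM", "TC")
PANELS = ("panel1", "panel2")
MARKERS = ("CK", "CD4", "CD8", "FOXP3", "PD1", "PDL1")
PANEL_MARKERS: dict[str, tuple[str, ...]] = {
    "panel1": ("CK", "CD4", "CD8", "FOXP3"),
    "panel2": ("CK", "FOXP3", "PD1", "PDL1"),
}

CELL_COLUMNS = ("cell_id", "x_um", "y_um", "region", "core_id", "patient_id", "panel")

PATIENT_COLUMNS = (
    "patient_id",
    "rfs_months",
    "event",
    "age_group",
    "gender",
    "histology",
    "smoking_index_group",
    "stage_group",
)

COVARIATE_VOCAB: dict[str, tuple[str, ...]] = {
    "age_group": ("<=65", ">65"),
    "gender": ("male", "female"),
    "histology": ("LUAD", "LUSC"),
    "smoking_index_group": ("<400", ">=400"),
    "stage_group": ("I-II", "III"),
}

SPLITS = ("train", "validation", "unassigned")


class FormatError(ValueError):
    """A table is structurally malformed (missing column, bad header)."""


class ValidationError(ValueError):
    """A table parsed but carries invalid values (bad vocabulary, bad range)."""


class PanelError(ValueError):
    """A phenotype gate requires a marker the panel does not stain."""


# ---------------------------------------------------------------------------
# Phenotype gates
# ---------------------------------------------------------------------------

def _b(cells: pd.DataFrame, marker: str) -> np.ndarray:
    return cells[marker].to_numpy(dtype=bool)


# name -> (required markers, gate predicate over the cell table)
_GATES: dict[str, tuple[tuple[str, ...], callable]] = {
    "Tumor": (("CK",), lambda c: _b(c, "CK")),
    "CD4all": (("CK", "CD4", "CD8"),
               lambda c: ~_b(c, "CK") & _b(c, "CD4") & ~_b(c, "CD8")),
    "CD8all": (("CK", "CD4", "CD8"),
               lambda c: ~_b(c, "CK") & _b(c, "CD8") & ~_b(c, "CD4")),
    "CD4Treg": (("CK", "CD4", "CD8", "FOXP3"),
                lambda c: ~_b(c, "CK") & _b(c, "CD4") & ~_b(c, "CD8") & _b(c, "FOXP3")),
    "CD4Tcon": (("CK", "CD4", "CD8", "FOXP3"),
                lambda c: ~_b(c, "CK") & _b(c, "CD4") & ~_b(c, "CD8") & ~_b(c, "FOXP3")),
    "CD8Treg": (("CK", "CD4", "CD8", "FOXP3"),
                lambda c: ~_b(c, "CK") & _b(c, "CD8") & ~_b(c, "CD4") & _b(c, "FOXP3")),
    "CD8Tcon": (("CK", "CD4", "CD8", "FOXP3"),
                lambda c: ~_b(c, "CK") & _b(c, "CD8") & ~_b(c, "CD4") & ~_b(c, "FOXP3")),
    "FOXP3pos": (("CK", "FOXP3"), lambda c: ~_b(c, "CK") & _b(c, "FOXP3")),
    "PD1pos": (("PD1",), lambda c: _b(c, "PD1")),
    "PDL1pos": (("PDL1",), lambda c: _b(c, "PDL1")),
}

PHENOTYPES = tuple(_GATES)


def phenotype_mask(cells: pd.DataFrame, phenotype: str) -> np.ndarray:
    """Boolean gate mask for ``phenotype`` over a cell table.

    Raises :class:`PanelError` naming the first marker the table lacks.
    """
    try:
        required, gate = _GATES[phenotype]
    except KeyError:
        raise ValueError(f"unknown phenotype {phenotype!r}; known: {PHENOTYPES}")
    for m in required:
        if m not in cells.columns:
            raise PanelError(
                f"phenotype {phenotype!r} requires marker {m!r} absent from this panel"
            )
    if len(cells) == 0:
        return np.zeros(0, dtype=bool)
    return gate(cells)


def gate_phenotype(cells: "pd.DataFrame | CoreWindow", phenotype: str) -> pd.DataFrame:
    """Return exactly the cells whose marker combination satisfies the gate."""
    df = cells.cells if isinstance(cells, CoreWindow) else cells
    return df.loc[phenotype_mask(df, phenotype)]


def phenotype_counts(cells: "pd.DataFrame | CoreWindow",
                     phenotypes: Sequence[str] | None = None) -> dict[str, int]:
    df = cells.cells if isinstance(cells, CoreWindow) else cells
    if phenotypes is None:
        panel_cols = set(df.columns)
        phenotypes = [p for p in PHENOTYPES
                      if set(_GATES[p][0]) <= panel_cols]
    return {p: int(phenotype_mask(df, p).sum()) for p in phenotypes}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: local-frame coordinates (μm) and marker calls."""

    cell_id: str
    x_um: float
    y_um: float
    markers: Mapping[str, bool]
    region: str
    core_id: str
    patient_id: str
    panel: str = "panel1"


@dataclass
class CoreWindow:
    """A rectangular tissue-core window holding segmented cells.

    Coordinates live in a local frame with the origin at the window corner;
    ``width_um`` × ``height_um`` define the bounds, and the area (mm²) is the
    denominator for densities.
    """

    core_id: str
    patient_id: str
    region: str
    panel: str = "panel1"
    width_um: float = 1000.0
    height_um: float = 1000.0
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.panel not in PANELS:
            raise ValidationError(f"panel must be one of {PANELS}, got {self.panel!r}")
        if not (self.width_um > 0 and self.height_um > 0):
            raise ValidationError("core window must have positive area")
        if self.cells is None or len(self.cells) == 0:
            cols = ["cell_id", "x_um", "y_um", *PANEL_MARKERS[self.panel]]
            self.cells = pd.DataFrame(columns=cols)
            return
        self.cells = self.cells.reset_index(drop=True)
        for m in PANEL_MARKERS[self.panel]:
            if m not in self.cells.columns:
                raise FormatError(f"panel {self.panel!r} cell table missing marker column {m!r}")
        xy = self.cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValidationError(f"core {self.core_id!r}: non-finite coordinates")
        if (xy[:, 0] < 0).any() or (xy[:, 0] > self.width_um).any() \
                or (xy[:, 1] < 0).any() or (xy[:, 1] > self.height_um).any():
            raise ValidationError(f"core {self.core_id!r}: coordinates outside window bounds")

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_table(self) -> pd.DataFrame:
        """Flatten to the on-disk cell-table layout."""
        out = self.cells.copy()
        out.insert(3, "region", self.region)
        out.insert(4, "core_id", self.core_id)
        out.insert(5, "patient_id", self.patient_id)
        out.insert(6, "panel", self.panel)
        return out


@dataclass(frozen=True)
class PatientRecord:
    """Survival outcome and clinical covariates for one patient."""

    patient_id: str
    rfs_months: float
    event: bool
    covariates: Mapping[str, str] = field(default_factory=dict)
    split: str = "unassigned"

    def __post_init__(self) -> None:
        if self.rfs_months < 0:
            raise ValidationError(f"patient {self.patient_id!r}: rfs_months < 0")
        if self.split not in SPLITS:
            raise ValidationError(f"split must be one of {SPLITS}")
        for key, value in self.covariates.items():
            vocab = COVARIATE_VOCAB.get(key)
            if vocab is not None and value not in vocab:
                raise ValidationError(
                    f"patient {self.patient_id!r}: covariate {key}={value!r} not in {vocab}")


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def _read_delimited(path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab from the header line
    return pd.read_csv(path, sep=None, engine="python")


def read_cell_table(path, panel: str | None = None,
                    window_um: tuple[float, float] = (1000.0, 1000.0)) -> list[CoreWindow]:
    """Read a delimited per-cell table and group it into :class:`CoreWindow` s.

    Parameters
    ----------
    path : str or file-like
        Comma- or tab-separated text with the columns
        ``cell_id,x_um,y_um,region,core_id,patient_id,panel`` plus the marker
        columns of the panel, coded 0/1.
    panel : str, optional
        If given, every row must belong to this panel; otherwise the panel is
        taken from the ``panel`` column (one panel per core).
    window_um : (width, height)
        Bounds of the local coordinate frame shared by all cores.
    """
    df = _read_delimited(path)
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"cell table missing mandatory column {col!r}")

    # line numbers are 1-based and include the header
    lines = df.index.to_numpy() + 2

    bad_region = ~df["region"].isin(REGIONS)
    if bad_region.any():
        raise ValidationError(
            f"unknown region label(s) {sorted(df.loc[bad_region, 'region'].unique())} "
            f"at line(s) {lines[bad_region.to_numpy()][:10].tolist()}")
    bad_panel = ~df["panel"].isin(PANELS)
    if bad_panel.any():
        raise ValidationError(
            f"unknown panel label(s) at line(s) {lines[bad_panel.to_numpy()][:10].tolist()}")
    if panel is not None and (df["panel"] != panel).any():
        off = (df["panel"] != panel).to_numpy()
        raise ValidationError(
            f"rows not in requested panel {panel!r} at line(s) {lines[off][:10].tolist()}")

    xy = df[["x_um", "y_um"]].apply(pd.to_numeric, errors="coerce").to_numpy()
    bad_xy = ~np.isfinite(xy).all(axis=1)
    if bad_xy.any():
        raise ValidationError(
            f"malformed coordinates at line(s) {lines[bad_xy][:10].tolist()}")
    df[["x_um", "y_um"]] = xy

    cores: list[CoreWindow] = []
    for core_id, sub in df.groupby("core_id", sort=True):
        for col in ("region", "patient_id", "panel"):
            if sub[col].nunique() != 1:
                raise ValidationError(f"core {core_id!r} has inconsistent {col!r} values")
        core_panel = sub["panel"].iloc[0]
        markers = PANEL_MARKERS[core_panel]
        for m in markers:
            if m not in sub.columns:
                raise FormatError(f"cell table missing marker column {m!r} for {core_panel}")
            vals = pd.to_numeric(sub[m], errors="coerce")
            if not vals.isin([0, 1]).all():
                bad = lines[df.index.isin(sub.index[~vals.isin([0, 1])])]
                raise ValidationError(
                    f"marker column {m!r} must be 0/1; bad line(s) {bad[:10].tolist()}")
        cells = sub[["cell_id", "x_um", "y_um", *markers]].copy()
        cells[list(markers)] = cells[list(markers)].astype(int)
        cores.append(CoreWindow(
            core_id=str(core_id),
            patient_id=str(sub["patient_id"].iloc[0]),
            region=str(sub["region"].iloc[0]),
            panel=str(core_panel),
            width_um=window_um[0],
            height_um=window_um[1],
            cells=cells,
        ))
    return cores


def write_cell_table(cores: Iterable[CoreWindow], path, sep: str = ",") -> None:
    tables = [c.to_table() for c in cores]
    out = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=CELL_COLUMNS)
    out.to_csv(path, sep=sep, index=False)


def read_patient_table(path) -> pd.DataFrame:
    """Read and validate a delimited per-patient clinical table."""
    df = _read_delimited(path)
    for col in ("patient_id", "rfs_months", "event"):
        if col not in df.columns:
            raise FormatError(f"patient table missing mandatory column {col!r}")
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id(s): {dups[:10]}")
    times = pd.to_numeric(df["rfs_months"], errors="coerce")
    if times.isna().any() or (times < 0).any():
        bad = (df.index[times.isna() | (times < 0)] + 2).tolist()
        raise ValidationError(f"invalid rfs_months at line(s) {bad[:10]}")
    events = pd.to_numeric(df["event"], errors="coerce")
    if not events.isin([0, 1]).all():
        raise ValidationError("event column must be 0/1")
    df["rfs_months"] = times
    df["event"] = events.astype(int)
    for col, vocab in COVARIATE_VOCAB.items():
        if col in df.columns and not df[col].isin(vocab).all():
            bad = sorted(set(df.loc[~df[col].isin(vocab), col]))
            raise ValidationError(f"covariate {col!r} has values outside {vocab}: {bad}")
    if "split" in df.columns and not df["split"].isin(SPLITS).all():
        raise ValidationError(f"split column values must be in {SPLITS}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df.reset_index(drop=True)


def write_patient_table(patients: pd.DataFrame, path, sep: str = ",") -> None:
    patients.to_csv(path, sep=sep, index=False)
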