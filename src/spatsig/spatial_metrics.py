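"""Per-core spatial immune metrics: density, mNND, and proximity score.

Three scalar summaries of a phenotyped point pattern are computed per core:

* **density** ``D(A)`` — cells of phenotype A per mm² of core area;
* **mean nearest-neighbor distance** ``N(A to B)`` — the average, over all A
  cells, of the Euclidean distance to the closest B cell (μm); smaller values
  indicate stronger spatial association;
* **proximity score** ``P(A to B)`` — the average, over all B cells, of the
  number of A cells within a fixed radius ``r`` (default 30 μm) of that B
  cell.

Conventions fixed here: "within radius" is closed (``<= r``); when the source
and target gates can overlap a cell is never paired with itself; no edge
correction is applied (cells near the core boundary simply have truncated
neighborhoods).  A metric whose denominator set is empty is *undefined* and
propagates as a missing value, never as zero.

The ``wrap`` option switches to toroidal (periodic) distances.  It exists for
validating the synthetic generator against closed-form Poisson expectations,
where edge effects would otherwise bias the comparison; the analysis pipeline
itself never wraps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_data import CoreWindow, PANEL_MARKERS, _GATES, phenotype_mask

DEFAULT_RADIUS_UM = 30.0

#: default metric plan per panel: densities plus all source→target pairs
DEFAULT_DENSITY_PHENOTYPES = {
    "panel1": ("CD4Treg", "CD8Treg"),
    "panel2": ("FOXP3pos", "PD1pos", "PDL1pos"),
}
DEFAULT_PAIRS = {
    "panel1": tuple(
        (s, t)
        for s in ("CD4Treg", "CD8Treg", "CD4Tcon")
        for t in ("Tumor", "CD4all", "CD8all")
    ),
    "panel2": (("PDL1pos", "PD1pos"),),
}


@dataclass(frozen=True)
class MetricValue:
    """One computed metric for one core.

    ``defined`` is False exactly when the formula's denominator set is empty
    (no source cells for mNND, no target cells for the proximity score); the
    value is then NaN.
    """

    metric: str                 # "D", "N" or "P"
    source: str
    target: str | None
    region: str
    core_id: str
    patient_id: str
    value: float
    n_source: int
    n_target: int | None = None
    radius_um: float | None = None
    defined: bool = True


def _points(core: CoreWindow, phenotype: str) -> tuple[np.ndarray, np.ndarray]:
    mask = phenotype_mask(core.cells, phenotype)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return idx, np.empty((0, 2))
    return idx, core.cells[["x_um", "y_um"]].to_numpy(dtype=float)[idx]


def _boxsize(core: CoreWindow, wrap: bool):
    if not wrap:
        return None
    return [core.width_um, core.height_um]


def density(core: CoreWindow, phenotype: str) -> MetricValue:
    """Cell density of ``phenotype`` in cells/mm²."""
    if core.area_mm2 <= 0:
        raise ValueError("core area must be positive")
    n = int(phenotype_mask(core.cells, phenotype).sum())
    return MetricValue(
        metric="D", source=phenotype, target=None, region=core.region,
        core_id=core.core_id, patient_id=core.patient_id,
        value=n / core.area_mm2, n_source=n,
    )


def mnnd(core: CoreWindow, source: str, target: str, wrap: bool = False) -> MetricValue:
    """Mean nearest-neighbor distance from ``source`` cells to ``target`` cells.

    Each source cell contributes its distance to the closest target cell that
    is not itself; source cells with no admissible neighbor (the sole target
    is the cell itself) are dropped from the mean.
    """
    idx_a, a = _points(core, source)
    idx_b, b = _points(core, target)
    base = dict(metric="N", source=source, target=target, region=core.region,
                core_id=core.core_id, patient_id=core.patient_id,
                n_source=len(idx_a), n_target=len(idx_b))
    if len(idx_a) == 0 or len(idx_b) == 0:
        return MetricValue(value=float("nan"), defined=False, **base)

    tree = cKDTree(b, boxsize=_boxsize(core, wrap))
    overlap = np.isin(idx_a, idx_b)
    if not overlap.any():
        dists, _ = tree.query(a, k=1)
        dists = np.asarray(dists, dtype=float)
    else:
        k = min(2, len(idx_b))
        d, j = tree.query(a, k=k)
        d = np.atleast_2d(np.asarray(d, dtype=float).reshape(len(idx_a), k))
        j = np.atleast_2d(np.asarray(j).reshape(len(idx_a), k))
        # nearest neighbor is the query cell itself -> take the next one
        self_hit = overlap & (idx_b[j[:, 0]] == idx_a)
        if k == 1:
            dists = np.where(self_hit, np.nan, d[:, 0])
        else:
            dists = np.where(self_hit, d[:, 1], d[:, 0])
    valid = np.isfinite(dists)
    if not valid.any():
        return MetricValue(value=float("nan"), defined=False, **base)
    return MetricValue(value=float(dists[valid].mean()), **base)


def proximity(core: CoreWindow, source: str, target: str,
              r: float = DEFAULT_RADIUS_UM, wrap: bool = False) -> MetricValue:
    """Mean count of ``source`` cells within radius ``r`` of each ``target`` cell."""
    if r <= 0:
        raise ValueError(f"radius must be positive, got {r}")
    idx_a, a = _points(core, source)
    idx_b, b = _points(core, target)
    base = dict(metric="P", source=source, target=target, region=core.region,
                core_id=core.core_id, patient_id=core.patient_id,
                n_source=len(idx_a), n_target=len(idx_b), radius_um=float(r))
    if len(idx_b) == 0:
        return MetricValue(value=float("nan"), defined=False, **base)
    if len(idx_a) == 0:
        return MetricValue(value=0.0, **base)
    tree = cKDTree(a, boxsize=_boxsize(core, wrap))
    counts = tree.query_ball_point(b, r, return_length=True).astype(float)
    counts -= np.isin(idx_b, idx_a)  # a cell never counts itself
    return MetricValue(value=float(counts.mean()), **base)


def metrics_for_core(core: CoreWindow,
                     pairs: Sequence[tuple[str, str]] | None = None,
                     density_phenotypes: Sequence[str] | None = None,
                     r: float = DEFAULT_RADIUS_UM) -> list[MetricValue]:
    """All metrics for one core in a deterministic order.

    Raises :class:`~spatsig.cell_data.PanelError` when a requested phenotype
    needs a marker the core's panel does not stain.
    """
    if pairs is None:
        pairs = DEFAULT_PAIRS[core.panel]
    if density_phenotypes is None:
        density_phenotypes = DEFAULT_DENSITY_PHENOTYPES[core.panel]
    out: list[MetricValue] = []
    for phen in density_phenotypes:
        out.append(density(core, phen))
    for s, t in pairs:
        out.append(mnnd(core, s, t))
    for s, t in pairs:
        out.append(proximity(core, s, t, r=r))
    return out


METRIC_TABLE_COLUMNS = ("patient_id", "core_id", "region", "metric", "source",
                        "target", "radius_um", "value", "n_source", "n_target",
                        "defined")


def metrics_table(cores: Iterable[CoreWindow],
                  pairs_by_panel: dict[str, Sequence[tuple[str, str]]] | None = None,
                  r: float = DEFAULT_RADIUS_UM) -> pd.DataFrame:
    """Long-format metric table over a collection of cores."""
    rows = []
    for core in cores:
        pairs = None if pairs_by_panel is None else pairs_by_panel.get(core.panel)
        for mv in metrics_for_core(core, pairs=pairs, r=r):
            rows.append({
                "patient_id": mv.patient_id, "core_id": mv.core_id,
                "region": mv.region, "metric": mv.metric, "source": mv.source,
                "target": mv.target if mv.target is not None else "",
                "radius_um": mv.radius_um if mv.radius_um is not None else np.nan,
                "value": mv.value, "n_source": mv.n_source,
                "n_target": mv.n_target if mv.n_target is not None else np.nan,
                "defined": mv.defined,
            })
    return pd.DataFrame(rows, columns=METRIC_TABLE_COLUMNS)
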