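"""End-to-end orchestration: simulate/read → metrics → features → split →
selection → signature → survival evaluation → report.

Every stage is deterministic given the configured seed; each stage failure is
re-raised with the stage name so a broken run names the step that broke.
Intermediate tables (metrics, features, scores, split, model, report) are
written to the output directory when one is configured.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cell_data, synthetic_cohort
from .cell_data import CoreWindow, gate_phenotype, phenotype_mask
from .feature_matrix import (build_feature_matrix, compare_groups,
                             dichotomize_feature)
from .selection_signature import (SelectionConfig, fit_signature,
                                  select_features, split_cohort)
from .spatial_metrics import DEFAULT_RADIUS_UM, metrics_table
from .survival_stats import (cox_fit, km_estimate, logrank, optimal_cutpoint,
                             time_dependent_auc)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    n_patients: int = 261
    seed: int = 0
    radius_um: float = DEFAULT_RADIUS_UM
    ratio: float = 0.7
    cutoff_policy: str = "xtile"
    horizons: tuple[float, ...] = (12.0, 36.0, 60.0)
    panels: tuple[str, ...] = ("panel1", "panel2")
    lasso_target: str = "cox"
    stratify_on: tuple[str, ...] = ("stage_group",)
    outdir: str | None = None
    write_cells: bool = False
    # optional external inputs; when set, simulation is skipped
    cells_path: str | None = None
    patients_path: str | None = None

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        h = list(self.horizons)
        if any(x <= 0 for x in h) or h != sorted(h):
            raise ValueError("horizons must be positive and ascending")


@dataclass
class RunReport:
    config: dict
    composition: dict
    selection: dict
    model: dict
    evaluation: dict
    panel2: dict | None
    n_feature_level_tests: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, set):
        return sorted(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


# ---------------------------------------------------------------------------
# Composition and panel-2 interplay
# ---------------------------------------------------------------------------

def composition_summary(cores: Sequence[CoreWindow]) -> pd.DataFrame:
    """Treg composition per region, pooled over panel-1 cores.

    Fractions of CD4+ and CD8+ Tregs among FOXP3+ (CK−) cells, and the
    FOXP3+ fraction within each T-cell lineage; missing when the denominator
    is zero.
    """
    rows = []
    for region in cell_data.REGIONS:
        cells = [c.cells for c in cores if c.panel == "panel1" and c.region == region]
        if not cells:
            continue
        pooled = pd.concat(cells, ignore_index=True)
        n = {p: int(phenotype_mask(pooled, p).sum())
             for p in ("FOXP3pos", "CD4Treg", "CD8Treg", "CD4all", "CD8all")}
        rows.append({
            "region": region,
            "n_foxp3": n["FOXP3pos"],
            "cd4treg_frac_of_tregs":
                n["CD4Treg"] / n["FOXP3pos"] if n["FOXP3pos"] else np.nan,
            "cd8treg_frac_of_tregs":
                n["CD8Treg"] / n["FOXP3pos"] if n["FOXP3pos"] else np.nan,
            "foxp3_frac_of_cd4": n["CD4Treg"] / n["CD4all"] if n["CD4all"] else np.nan,
            "foxp3_frac_of_cd8": n["CD8Treg"] / n["CD8all"] if n["CD8all"] else np.nan,
        })
    return pd.DataFrame(rows)


def panel2_interplay(features: pd.DataFrame, patients: pd.DataFrame,
                     foxp3_grouping: str = "xtile",
                     min_group_frac: float = 0.1) -> dict:
    """Checkpoint interplay stratified by FOXP3+ cell abundance.

    Patients are grouped high/low on their mean FOXP3+ density; the PD-L1→PD-1
    mNND and proximity score are compared between the groups per region
    (Mann–Whitney), and each metric is also dichotomized against survival.
    """
    pts = patients.set_index("patient_id")
    dens_cols = [c for c in ("D(FOXP3pos)@IM", "D(FOXP3pos)@TC") if c in features.columns]
    if not dens_cols:
        raise ValueError("no FOXP3+ density features present; is panel 2 included?")
    foxp3 = features[dens_cols].mean(axis=1)
    common = foxp3.dropna().index.intersection(pts.index)
    foxp3 = foxp3.loc[common]
    times = pts.loc[common, "rfs_months"].to_numpy(dtype=float)
    events = pts.loc[common, "event"].to_numpy(dtype=int)
    grouping = dichotomize_feature(foxp3, times, events, policy=foxp3_grouping,
                                   min_group_frac=min_group_frac)
    labels = grouping.labels
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise ValueError("FOXP3 grouping emptied one arm")

    out = {"foxp3_cutoff": grouping.cutoff,
           "n_high": int((labels == "high").sum()),
           "n_low": int((labels == "low").sum()),
           "comparisons": {}, "survival": {}}
    for region in ("IM", "TC"):
        for feat in (f"N(PDL1pos_to_PD1pos)@{region}", f"P(PDL1pos_to_PD1pos)@{region}"):
            if feat not in features.columns:
                continue
            v = features.loc[common, feat]
            hi, lo = v[labels == "high"].dropna(), v[labels == "low"].dropna()
            cmp = compare_groups(hi, lo)
            out["comparisons"][feat] = {
                "median_high": float(hi.median()), "median_low": float(lo.median()),
                "u_statistic": cmp.u_statistic, "p_value": cmp.p_value,
            }
            defined = v.dropna().index
            if len(defined) >= 20:
                dt = pts.loc[defined, "rfs_months"].to_numpy(dtype=float)
                de = pts.loc[defined, "event"].to_numpy(dtype=int)
                try:
                    d = dichotomize_feature(v.loc[defined], dt, de, policy="xtile",
                                            min_group_frac=min_group_frac)
                    lr = logrank(dt, de, d.labels.to_numpy())
                    out["survival"][feat] = {"cutoff": d.cutoff,
                                             "logrank_chi2": lr.chi_square,
                                             "logrank_p": lr.p_value}
                except ValueError as exc:
                    out["survival"][feat] = {"error": str(exc)}
    return out


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def _km_median(times, events):
    km = km_estimate(times, events)
    return km.median


def _evaluate_subset(scores: pd.Series, groups: pd.Series, pts: pd.DataFrame,
                     horizons: Sequence[float]) -> dict:
    times = pts["rfs_months"].to_numpy(dtype=float)
    events = pts["event"].to_numpy(dtype=int)
    g = groups.loc[pts["patient_id"]].to_numpy()
    res: dict = {"n": len(pts), "n_events": int(events.sum())}
    if len(set(g)) == 2:
        lr = logrank(times, events, g)
        res["logrank_chi2"] = lr.chi_square
        res["logrank_p"] = lr.p_value
        res["median_rfs_high"] = _km_median(times[g == "high"], events[g == "high"])
        res["median_rfs_low"] = _km_median(times[g == "low"], events[g == "low"])
    res["auc"] = {}
    s = scores.loc[pts["patient_id"]].to_numpy()
    for h in horizons:
        try:
            res["auc"][f"{int(h)}mo"] = time_dependent_auc(s, times, events, h).auc
        except ValueError as exc:
            res["auc"][f"{int(h)}mo"] = None
            logger.warning("AUC at %s months unavailable: %s", h, exc)
    return res


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full study design and return a structured report."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    with _stage("simulate/ingest"):
        if config.cells_path and config.patients_path:
            cores = cell_data.read_cell_table(config.cells_path)
            patients = cell_data.read_patient_table(config.patients_path)
            metrics = metrics_table(cores, r=config.radius_um)
            features = build_feature_matrix(metrics, patients)
            manifest = {"source": "external", "cells": str(config.cells_path)}
        else:
            cohort = synthetic_cohort.simulate_cohort(
                config.n_patients, seed=config.seed, panels=config.panels,
                r_um=config.radius_um)
            cores, patients = cohort.cores, cohort.patients
            metrics, features = cohort.metrics, cohort.features
            manifest = cohort.manifest
        if outdir and config.write_cells:
            cell_data.write_cell_table(cores, outdir / "cells.csv")
        if outdir:
            cell_data.write_patient_table(patients, outdir / "patients.csv")
            metrics.to_csv(outdir / "metrics.csv", index=False)
            features.to_csv(outdir / "features.csv")

    with _stage("composition"):
        composition = composition_summary(cores)

    with _stage("split"):
        split = split_cohort(patients, ratio=config.ratio,
                             stratify_on=config.stratify_on, seed=config.seed)
        patients = patients.copy()
        patients["split"] = split.to_numpy()
        if (patients["split"] == "validation").sum() == 0:
            raise ValueError("validation split is empty")
        if outdir:
            patients[["patient_id", "split"]].to_csv(outdir / "split.csv", index=False)

    train = patients[patients["split"] == "train"]
    valid = patients[patients["split"] == "validation"]
    X_train = features.loc[train["patient_id"]]

    with _stage("selection"):
        sel = select_features(
            X_train, train["rfs_months"], train["event"],
            SelectionConfig(lasso_target=config.lasso_target, seed=config.seed))
        if not sel.intersection:
            raise ValueError("empty three-algorithm intersection; no signature "
                             "can be fitted")
        if outdir:
            (outdir / "selection.json").write_text(json.dumps({
                "lasso": sel.lasso_features, "xgb": sel.xgb_top, "rf": sel.rf_top,
                "intersection": sorted(sel.intersection),
                "lasso_alpha": sel.lasso_alpha}, indent=2))

    with _stage("signature"):
        model = fit_signature(X_train, train["rfs_months"], train["event"],
                              sel.ordered_intersection,
                              meta={"seed": config.seed,
                                    "lasso_target": config.lasso_target})
        scores = model.score(features)
        groups = pd.Series(np.where(scores > model.cutoff, "high", "low"),
                           index=scores.index)
        if outdir:
            (outdir / "sis_model.json").write_text(model.to_json())
            pd.DataFrame({"patient_id": scores.index, "sis": scores.to_numpy(),
                          "group": groups.to_numpy()}).to_csv(
                outdir / "sis_scores.csv", index=False)

    with _stage("evaluation"):
        evaluation = {
            "train": _evaluate_subset(scores, groups, train, config.horizons),
            "validation": _evaluate_subset(scores, groups, valid, config.horizons),
            "entire": _evaluate_subset(scores, groups, patients, config.horizons),
        }
        # multivariate Cox: stage group + SIS group, entire cohort
        Xc = pd.DataFrame({
            "stage_III": (patients["stage_group"] == "III").astype(float).to_numpy(),
            "sis_high": (groups.loc[patients["patient_id"]] == "high")
                        .astype(float).to_numpy(),
        })
        fit = cox_fit(Xc, patients["rfs_months"], patients["event"])
        evaluation["multivariate_cox"] = {
            term: {"hr": float(fit.hazard_ratios[term]),
                   "ci": [float(fit.ci_lower[term]), float(fit.ci_upper[term])],
                   "p": float(fit.p_values[term])}
            for term in Xc.columns
        }

    panel2 = None
    if "panel2" in config.panels:
        with _stage("panel2-interplay"):
            panel2 = panel2_interplay(features, patients)

    n_tests = len([c for c in features.columns]) \
        + (len(panel2["comparisons"]) if panel2 else 0)

    report = RunReport(
        config={**dataclasses.asdict(config), "manifest": manifest},
        composition=composition.to_dict(orient="records"),
        selection={"lasso": sel.lasso_features, "xgb": sel.xgb_top,
                   "rf": sel.rf_top, "intersection": sorted(sel.intersection),
                   "lasso_alpha": sel.lasso_alpha},
        model={"features": model.features,
               "coefficients": model.coefficients.tolist(),
               "cutoff": model.cutoff},
        evaluation=evaluation,
        panel2=panel2,
        n_feature_level_tests=n_tests,
    )
    if outdir:
        (outdir / "report.json").write_text(report.to_json())
    return report
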