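"""Synthetic mIF cohort generator with known spatial and prognostic ground truth.

The generator emulates, at the order-of-magnitude level of real TMA data, a
cohort of operable NSCLC patients each contributing one invasive-margin (IM)
and one tumor-center (TC) core per staining panel (1 mm × 1 mm windows):

* **tumor cells** — a parent–offspring (Thomas-type) clustered process:
  Poisson parents, each offspring displaced from a uniformly chosen parent by
  an isotropic Gaussian, wrapped toroidally so the marginal intensity is
  exactly the requested one;
* **immune cells** — Poisson counts (mean = intensity × area); each cell is
  placed by a mixture controlled by an attraction coefficient ρ ∈ [−1, 1]
  toward a target phenotype: with probability \\|ρ\\| the cell is displaced by
  an isotropic Gaussian (sd ``cluster_sigma``) from a uniformly chosen target
  cell (toward when ρ > 0; placed by rejection away from all targets within
  2·``cluster_sigma`` when ρ < 0), otherwise uniform in the window.  ρ = 0 is
  complete spatial randomness;
* **survival** — exponential recurrence times with hazard
  ``baseline_hazard · exp(Σ β · z)`` over z-scored spatial features computed
  by the real metric code, plus an additive stage-III log-hazard; independent
  exponential censoring truncated at the maximum follow-up.

Everything is driven by one :class:`numpy.random.Generator`, so an identical
seed reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .cell_data import CoreWindow, PANEL_MARKERS
from .feature_matrix import build_feature_matrix
from .spatial_metrics import DEFAULT_RADIUS_UM, metrics_table

logger = logging.getLogger(__name__)

# marker columns switched on per generator phenotype label
PHENOTYPE_MARKERS: dict[str, frozenset] = {
    "Tumor": frozenset({"CK"}),
    "CD4Tcon": frozenset({"CD4"}),
    "CD4Treg": frozenset({"CD4", "FOXP3"}),
    "CD8Tcon": frozenset({"CD8"}),
    "CD8Treg": frozenset({"CD8", "FOXP3"}),
    "FOXP3pos": frozenset({"FOXP3"}),
    "PD1pos": frozenset({"PD1"}),
    "PDL1pos": frozenset({"PDL1"}),
}

# placement order: attraction targets must already be on the slide
PLACEMENT_ORDER = ("Tumor", "CD4Tcon", "CD4Treg", "CD8Tcon", "CD8Treg",
                   "FOXP3pos", "PD1pos", "PDL1pos")

# composite targets resolve to unions of generator labels
_TARGET_LABELS: dict[str, tuple[str, ...]] = {
    "CD4all": ("CD4Tcon", "CD4Treg"),
    "CD8all": ("CD8Tcon", "CD8Treg"),
}


@dataclass
class SpatialSimParams:
    """Per-core point-process parameters.

    ``intensities`` are in cells/mm²; ``attraction`` maps (source, target)
    phenotype pairs to ρ ∈ [−1, 1]; ``cluster_sigma`` (μm) is the Gaussian
    displacement scale of the attraction mechanism; tumor cells use their own
    Thomas-process parameters.
    """

    width_um: float = 1000.0
    height_um: float = 1000.0
    intensities: Mapping[str, float] = field(default_factory=dict)
    attraction: Mapping[tuple[str, str], float] = field(default_factory=dict)
    cluster_sigma: float = 20.0
    tumor_parent_intensity: float = 10.0    # parents/mm²
    tumor_cluster_sigma: float = 35.0       # μm
    panel: str = "panel1"

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("window area must be positive")
        for phen, lam in self.intensities.items():
            if lam < 0:
                raise ValueError(f"intensity for {phen!r} must be >= 0")
        for pair, rho in self.attraction.items():
            if abs(rho) > 1:
                raise ValueError(f"|rho| must be <= 1 for {pair}")

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um / 1e6


@dataclass
class HazardSimParams:
    """Exponential recurrence-time model with planted feature effects.

    ``betas`` are log-hazard coefficients on z-scored spatial features (the
    defaults plant effects on the four signature features, with magnitudes
    taken from typical univariate hazard ratios of such features);
    ``stage_beta`` is the additive log-hazard of stage III disease.
    """

    baseline_hazard: float = 0.010          # events/month
    betas: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BETAS))
    stage_beta: float = float(np.log(2.26))
    censor_rate: float = 0.012              # events/month
    max_followup: float = 84.0              # months

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ValueError("baseline hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censoring rate must be >= 0")
        if self.max_followup <= 0:
            raise ValueError("maximum follow-up must be positive")


# Planted per-SD log-hazards on the four signature features.  Magnitudes are
# half the typical high-vs-low group log-HRs of such features: a group
# contrast spans roughly two standard deviations, so the per-SD effect is
# about half the contrast.  The resulting dichotomized-signature hazard ratio
# lands in the 2-4 range seen for published spatial signatures.
DEFAULT_BETAS: dict[str, float] = {
    "P(CD8Treg_to_CD4all)@IM": 0.32,
    "P(CD8Treg_to_Tumor)@IM": 0.35,
    "N(CD4Treg_to_Tumor)@IM": -0.40,
    "N(CD4Tcon_to_Tumor)@IM": -0.46,
}


# ---------------------------------------------------------------------------
# Core simulation
# ---------------------------------------------------------------------------

def _wrap(xy: np.ndarray, w: float, h: float) -> np.ndarray:
    xy[:, 0] %= w
    xy[:, 1] %= h
    return xy


def _simulate_tumor(params: SpatialSimParams, rng: np.random.Generator) -> np.ndarray:
    w, h = params.width_um, params.height_um
    lam = params.intensities.get("Tumor", 0.0)
    n = rng.poisson(lam * params.area_mm2)
    if n == 0:
        return np.empty((0, 2))
    n_parents = rng.poisson(params.tumor_parent_intensity * params.area_mm2)
    if n_parents == 0:
        return rng.uniform((0, 0), (w, h), size=(n, 2))
    parents = rng.uniform((0, 0), (w, h), size=(n_parents, 2))
    assign = rng.integers(0, n_parents, size=n)
    xy = parents[assign] + rng.normal(0.0, params.tumor_cluster_sigma, size=(n, 2))
    return _wrap(xy, w, h)


def _resolve_targets(target: str, placed: dict[str, np.ndarray]) -> np.ndarray:
    labels = _TARGET_LABELS.get(target, (target,))
    parts = [placed[l] for l in labels if l in placed and len(placed[l])]
    if not parts:
        return np.empty((0, 2))
    return np.vstack(parts)


def _place_immune(n: int, targets: Sequence[tuple[np.ndarray, float]],
                  params: SpatialSimParams, rng: np.random.Generator) -> np.ndarray:
    """Mixture placement: attraction/repulsion toward targets, else uniform."""
    w, h = params.width_um, params.height_um
    sigma = params.cluster_sigma
    if n == 0:
        return np.empty((0, 2))
    mech = np.full(n, -1)
    if targets:
        u = rng.uniform(size=(n, len(targets)))
        for k, (_, rho) in enumerate(targets):
            free = mech < 0
            mech[free & (u[:, k] < abs(rho))] = k
    xy = np.empty((n, 2))
    uniform_mask = mech < 0
    m = int(uniform_mask.sum())
    if m:
        xy[uniform_mask] = rng.uniform((0, 0), (w, h), size=(m, 2))
    for k, (tc, rho) in enumerate(targets):
        sel = np.flatnonzero(mech == k)
        if sel.size == 0:
            continue
        if rho > 0:
            ti = rng.integers(0, len(tc), size=sel.size)
            pts = tc[ti] + rng.normal(0.0, sigma, size=(sel.size, 2))
            xy[sel] = _wrap(pts, w, h)
        else:
            tree = cKDTree(tc)
            for i in sel:
                pt = rng.uniform((0, 0), (w, h))
                for _ in range(50):
                    d, _j = tree.query(pt)
                    if d > 2 * sigma:
                        break
                    pt = rng.uniform((0, 0), (w, h))
                xy[i] = pt
    return xy


def simulate_core(params: SpatialSimParams, region: str,
                  rng: np.random.Generator,
                  core_id: str = "C1", patient_id: str = "P1") -> CoreWindow:
    """Simulate one phenotyped core as a :class:`CoreWindow`.

    Cell counts per phenotype are Poisson with mean intensity × area; tumor
    cells come from the clustered process, immune cells from the attraction
    mixture.  An attraction toward a phenotype with zero cells on the slide
    falls back to uniform placement with a logged warning.
    """
    placed: dict[str, np.ndarray] = {}
    rows: list[pd.DataFrame] = []
    markers = PANEL_MARKERS[params.panel]
    for phen in PLACEMENT_ORDER:
        if phen not in params.intensities:
            continue
        if phen == "Tumor":
            xy = _simulate_tumor(params, rng)
        else:
            n = rng.poisson(params.intensities[phen] * params.area_mm2)
            targets = []
            for (src, tgt), rho in params.attraction.items():
                if src != phen or rho == 0:
                    continue
                tc = _resolve_targets(tgt, placed)
                if len(tc) == 0:
                    logger.warning(
                        "core %s: attraction %s->%s requested but no %s cells; "
                        "falling back to uniform", core_id, src, tgt, tgt)
                    continue
                targets.append((tc, rho))
            xy = _place_immune(n, targets, params, rng)
        placed[phen] = xy
        if len(xy) == 0:
            continue
        on = PHENOTYPE_MARKERS[phen]
        block = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1]})
        for m in markers:
            block[m] = int(m in on)
        rows.append(block)
    if rows:
        cells = pd.concat(rows, ignore_index=True)
        cells.insert(0, "cell_id", [f"{core_id}-{i}" for i in range(len(cells))])
    else:
        cells = pd.DataFrame(columns=["cell_id", "x_um", "y_um", *markers])
    return CoreWindow(core_id=core_id, patient_id=patient_id, region=region,
                      panel=params.panel, width_um=params.width_um,
                      height_um=params.height_um, cells=cells)


# ---------------------------------------------------------------------------
# Cohort-level samplers
# ---------------------------------------------------------------------------

def default_spatial_sampler(rng: np.random.Generator) -> dict[str, SpatialSimParams]:
    """Per-patient spatial parameters for both panels.

    Intensities get a log-normal patient effect; attraction coefficients are
    drawn uniformly so the cohort spans weak to strong spatial coupling.  In
    panel 2 the FOXP3+ abundance and the PD-L1→PD-1 attraction share one
    latent draw, planting the association between Treg burden and checkpoint
    interplay.  CD4+ vs CD8+ Treg intensities are set so CD4+ Tregs dominate
    the regulatory compartment (~90%), as in real NSCLC tissue.
    """

    def jit() -> float:
        return float(np.exp(rng.normal(0.0, 0.25)))

    panel1 = SpatialSimParams(
        panel="panel1",
        intensities={
            "Tumor": 800.0 * jit(),
            "CD4Tcon": 300.0 * jit(),
            "CD4Treg": 150.0 * jit(),
            "CD8Tcon": 200.0 * jit(),
            "CD8Treg": 15.0 * jit(),
        },
        attraction={
            ("CD4Treg", "Tumor"): rng.uniform(0.0, 0.8),
            ("CD4Tcon", "Tumor"): rng.uniform(0.0, 0.8),
            ("CD8Treg", "Tumor"): rng.uniform(0.0, 0.8),
            ("CD8Treg", "CD4all"): rng.uniform(0.0, 0.8),
        },
    )
    latent = rng.uniform()
    panel2 = SpatialSimParams(
        panel="panel2",
        intensities={
            "Tumor": 800.0 * jit(),
            "FOXP3pos": 60.0 + 240.0 * latent,
            "PD1pos": 200.0 * jit(),
            "PDL1pos": 250.0 * jit(),
        },
        attraction={("PDL1pos", "PD1pos"): 0.8 * latent},
    )
    return {"panel1": panel1, "panel2": panel2}


#: marginal covariate frequencies of an operable NSCLC surgical cohort
COVARIATE_FREQS: dict[str, tuple[tuple[str, float], ...]] = {
    "age_group": (("<=65", 0.678), (">65", 0.322)),
    "gender": (("male", 0.644), ("female", 0.356)),
    "histology": (("LUAD", 0.659), ("LUSC", 0.341)),
    "smoking_index_group": (("<400", 0.567), (">=400", 0.433)),
    "stage_group": (("I-II", 0.816), ("III", 0.184)),
}


def sample_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, levels in COVARIATE_FREQS.items():
        labels = [l for l, _ in levels]
        probs = [p for _, p in levels]
        cols[name] = rng.choice(labels, size=n, p=probs)
    return pd.DataFrame(cols)


def simulate_survival(linear_predictor: np.ndarray, hazard: HazardSimParams,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Draw (time, event) from the exponential hazard and censoring model."""
    lp = np.asarray(linear_predictor, dtype=float)
    rate = hazard.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if hazard.censor_rate == 0:
        t_cens = np.full_like(t_event, hazard.max_followup)
    else:
        scale = 0.0 if np.isinf(hazard.censor_rate) else 1.0 / hazard.censor_rate
        t_cens = np.minimum(rng.exponential(scale, size=len(lp)), hazard.max_followup)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


@dataclass
class Cohort:
    """One synthetic cohort: cores, clinical table, features and ground truth."""

    cores: list[CoreWindow]
    patients: pd.DataFrame
    features: pd.DataFrame
    metrics: pd.DataFrame
    true_betas: dict[str, float]
    manifest: dict


def simulate_cohort(n_patients: int,
                    spatial_sampler: Callable[[np.random.Generator],
                                              dict[str, SpatialSimParams]] | None = None,
                    hazard: HazardSimParams | None = None,
                    seed: int = 0,
                    panels: Sequence[str] = ("panel1", "panel2"),
                    r_um: float = DEFAULT_RADIUS_UM) -> Cohort:
    """Simulate a full cohort: cores for both regions, features, survival.

    The true per-patient feature vector is computed by the actual metric code
    (not by a shortcut), so downstream stages can be validated end-to-end
    against the planted ``hazard.betas``.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    hazard = hazard or HazardSimParams()
    sampler = spatial_sampler or default_spatial_sampler

    cores: list[CoreWindow] = []
    for i in range(n_patients):
        pid = f"PT{i + 1:04d}"
        per_panel = sampler(rng)
        for panel in panels:
            params = per_panel[panel]
            for region in ("IM", "TC"):
                cores.append(simulate_core(
                    params, region, rng,
                    core_id=f"{pid}-{panel}-{region}", patient_id=pid))

    covs = sample_covariates(n_patients, rng)
    metrics = metrics_table(cores, r=r_um)
    features = build_feature_matrix(metrics)

    lp = np.zeros(n_patients)
    for name, beta in hazard.betas.items():
        if name not in features.columns:
            raise ValueError(f"planted effect on unknown feature {name!r}")
        v = features[name].to_numpy(dtype=float)
        mu, sd = np.nanmean(v), np.nanstd(v)
        z = (v - mu) / (sd if sd > 0 else 1.0)
        lp += beta * np.nan_to_num(z)      # missing feature -> population mean
    lp += hazard.stage_beta * (covs["stage_group"] == "III").to_numpy(dtype=float)

    time, event = simulate_survival(lp, hazard, rng)
    patients = pd.DataFrame({
        "patient_id": features.index.to_numpy(),
        "rfs_months": time,
        "event": event,
        **{c: covs[c].to_numpy() for c in covs.columns},
        "split": "unassigned",
    })
    manifest = {
        "seed": seed,
        "n_patients": n_patients,
        "panels": list(panels),
        "radius_um": r_um,
        "hazard": {
            "baseline_hazard": hazard.baseline_hazard,
            "betas": dict(hazard.betas),
            "stage_beta": hazard.stage_beta,
            "censor_rate": hazard.censor_rate,
            "max_followup": hazard.max_followup,
        },
        "sampler": getattr(sampler, "__name__", repr(sampler)),
    }
    return Cohort(cores=cores, patients=patients, features=features,
                  metrics=metrics, true_betas=dict(hazard.betas),
                  manifest=manifest)


def simulate_feature_cohort(n_patients: int,
                            betas: Mapping[str, float],
                            n_null: int = 0,
                            hazard: HazardSimParams | None = None,
                            seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lightweight cohort for statistical validation of the modelling stages.

    Features are independent standard normals (already on the z-scale the
    hazard model expects): the named ``betas`` features carry the planted
    effects and ``n_null`` extra features carry none.  Spatial structure is
    bypassed on purpose — this isolates the survival-modelling machinery so
    power and coverage can be checked at many replicates cheaply.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    rng = np.random.default_rng(seed)
    hazard = hazard or HazardSimParams(stage_beta=0.0)
    names = list(betas) + [f"null_{j:02d}" for j in range(n_null)]
    X = pd.DataFrame(rng.standard_normal((n_patients, len(names))), columns=names,
                     index=[f"PT{i + 1:04d}" for i in range(n_patients)])
    X.index.name = "patient_id"
    lp = X[list(betas)].to_numpy() @ np.asarray(list(betas.values()))
    time, event = simulate_survival(lp, hazard, rng)
    patients = pd.DataFrame({
        "patient_id": X.index.to_numpy(),
        "rfs_months": time,
        "event": event,
    })
    return X, patients
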