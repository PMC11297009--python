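"""Feature selection by three-algorithm intersection and the spatial immune signature (SIS).

Selection runs three learners on the training split and intersects their
shortlists: (i) an L1-penalized Cox model (penalty chosen by 10-fold
cross-validated partial-likelihood deviance; up to ten nonzero-coefficient
features ranked by |coefficient|), (ii) gradient boosting (XGBoost) on the
binary recurrence indicator ranked by gain importance, and (iii) a random
forest on the same target ranked by impurity importance, each truncated to
its top ten.  The SIS is then the linear score
``Σ coefficient × feature`` whose coefficients are the multivariate Cox
estimates of the intersected features on the training split, dichotomized at
the outcome-driven optimal cutpoint of the training scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from xgboost import XGBClassifier

from .feature_matrix import Preprocessor
from .survival_stats import cox_fit, optimal_cutpoint

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cohort splitting
# ---------------------------------------------------------------------------

def split_cohort(patients: pd.DataFrame, ratio: float = 0.7,
                 stratify_on: Sequence[str] = ("stage_group",),
                 seed: int = 0) -> pd.Series:
    """Stratified random train/validation split.

    The training size is exactly ``round(ratio * n)``; per-stratum training
    counts are allocated by largest remainder so category proportions match
    between the splits to within one patient.  Strata smaller than 2 are
    merged into the largest stratum with a warning.
    """
    if not 0 < ratio < 1:
        raise ValueError(f"split ratio must be in (0, 1), got {ratio} "
                         "(ratio 1.0 would leave the validation split empty)")
    rng = np.random.default_rng(seed)
    n = len(patients)
    stratify_on = [c for c in stratify_on if c in patients.columns]
    if stratify_on:
        keys = patients[stratify_on].astype(str).agg("|".join, axis=1)
    else:
        keys = pd.Series(["all"] * n, index=patients.index)
    counts = keys.value_counts()
    if (counts < 2).any():
        small = counts.index[counts < 2]
        biggest = counts.idxmax()
        logger.warning("merging stratum(s) %s (<2 patients) into %r",
                       list(small), biggest)
        keys = keys.replace({s: biggest for s in small})
        counts = keys.value_counts()

    n_train_total = int(round(ratio * n))
    strata = list(counts.index)
    exact = np.array([ratio * counts[s] for s in strata])
    base = np.floor(exact).astype(int)
    short = n_train_total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:short]:
        base[i] += 1

    split = pd.Series("validation", index=patients.index, dtype=object)
    for s, k in zip(strata, base):
        members = np.flatnonzero((keys == s).to_numpy())
        chosen = rng.permutation(members)[:k]
        split.iloc[chosen] = "train"
    split.name = "split"
    return split


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionConfig:
    lasso_target: str = "cox"           # "cox" or "logistic"
    n_top: int = 10
    cv_folds: int = 10
    n_alphas: int = 50
    alpha_min_ratio: float = 0.01
    xgb_params: dict = field(default_factory=lambda: {
        "n_estimators": 200, "max_depth": 3, "learning_rate": 0.1,
        "subsample": 1.0, "eval_metric": "logloss"})
    rf_params: dict = field(default_factory=lambda: {
        "n_estimators": 500, "min_samples_leaf": 3})
    seed: int = 0


@dataclass
class SelectionResult:
    lasso_features: list[str]
    xgb_top: list[str]
    rf_top: list[str]
    intersection: set[str]
    config: SelectionConfig
    lasso_alpha: float | None = None

    @property
    def ordered_intersection(self) -> list[str]:
        return [f for f in self.lasso_features if f in self.intersection]


def intersect_rankings(*ranked_lists: Sequence[str]) -> set[str]:
    """Plain set intersection of ranked shortlists."""
    out = set(ranked_lists[0])
    for lst in ranked_lists[1:]:
        out &= set(lst)
    return out


def _breslow_loglik(lp: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Log partial likelihood of a fixed linear predictor (Breslow ties)."""
    order = np.argsort(-times, kind="stable")
    lp, t, e = lp[order], times[order], events[order]
    # cumulative log-sum-exp over the risk set {j : t_j >= t_i}
    running = np.logaddexp.accumulate(lp)
    # subjects tied on time share the full tied risk set
    risk = np.empty_like(running)
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        risk[i:j + 1] = running[j]
        i = j + 1
    mask = e == 1
    return float((lp[mask] - risk[mask]).sum())


def _lasso_cox(X: pd.DataFrame, times: np.ndarray, events: np.ndarray,
               config: SelectionConfig) -> tuple[list[str], float]:
    y = Surv.from_arrays(events.astype(bool), times)
    full = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=config.n_alphas,
                                  alpha_min_ratio=config.alpha_min_ratio,
                                  normalize=False, fit_baseline_model=False)
    full.fit(X.to_numpy(), y)
    alphas = np.asarray(full.alphas_)

    n = len(X)
    folds = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    deviance = np.zeros(len(alphas))
    for tr, te in folds.split(X):
        if events[te].sum() == 0 or events[tr].sum() == 0:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, normalize=False,
                                   fit_baseline_model=False)
        m.fit(X.iloc[tr].to_numpy(), Surv.from_arrays(events[tr].astype(bool), times[tr]))
        coefs = np.zeros((X.shape[1], len(alphas)))
        fitted = np.asarray(m.alphas_)
        # map fitted path back onto the requested grid (coxnet may stop early)
        for j, a in enumerate(alphas):
            k = int(np.argmin(np.abs(fitted - a)))
            coefs[:, j] = m.coef_[:, k]
        lp_te = X.iloc[te].to_numpy() @ coefs
        for j in range(len(alphas)):
            deviance[j] += -2.0 * _breslow_loglik(lp_te[:, j], times[te], events[te])
    best = int(np.argmin(deviance))
    coef = full.coef_[:, best]
    nonzero = np.flatnonzero(coef != 0)
    ranked = sorted(nonzero, key=lambda i: -abs(coef[i]))[:config.n_top]
    return [X.columns[i] for i in ranked], float(alphas[best])


def _lasso_logistic(X: pd.DataFrame, events: np.ndarray,
                    config: SelectionConfig) -> tuple[list[str], float]:
    model = LogisticRegressionCV(penalty="l1", solver="liblinear",
                                 Cs=config.n_alphas, cv=config.cv_folds,
                                 random_state=config.seed, max_iter=2000)
    model.fit(X.to_numpy(), events)
    coef = model.coef_.ravel()
    nonzero = np.flatnonzero(coef != 0)
    ranked = sorted(nonzero, key=lambda i: -abs(coef[i]))[:config.n_top]
    return [X.columns[i] for i in ranked], float(model.C_[0])


def select_features(X: pd.DataFrame, times, events,
                    config: SelectionConfig | None = None) -> SelectionResult:
    """Run the three learners on the training split and intersect their shortlists.

    ``X`` is the raw training feature matrix; median imputation and z-scoring
    are fitted here (training data only).  An empty intersection is returned
    with a warning — the caller decides whether the pipeline can continue.
    """
    config = config or SelectionConfig()
    if len(X) < 20:
        raise ValueError(f"need at least 20 training patients, got {len(X)}")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)

    pre = Preprocessor.fit(X)
    Z = pre.transform(X)

    if config.lasso_target == "cox":
        lasso_features, alpha = _lasso_cox(Z, t, e, config)
    elif config.lasso_target == "logistic":
        lasso_features, alpha = _lasso_logistic(Z, e, config)
    else:
        raise ValueError("lasso_target must be 'cox' or 'logistic'")

    xgb = XGBClassifier(random_state=config.seed, n_jobs=1, **config.xgb_params)
    xgb.fit(Z, e)
    gain = xgb.get_booster().get_score(importance_type="gain")
    xgb_top = [f for f, _ in sorted(gain.items(), key=lambda kv: -kv[1])][:config.n_top]

    rf = RandomForestClassifier(random_state=config.seed, n_jobs=1, **config.rf_params)
    rf.fit(Z, e)
    imp = rf.feature_importances_
    rf_order = np.argsort(-imp, kind="stable")[:config.n_top]
    rf_top = [Z.columns[i] for i in rf_order if imp[i] > 0]

    inter = intersect_rankings(lasso_features, xgb_top, rf_top) if lasso_features else set()
    if not inter:
        logger.warning("empty feature intersection; downstream signature fitting "
                       "will not be possible")
    return SelectionResult(lasso_features=lasso_features, xgb_top=xgb_top,
                           rf_top=rf_top, intersection=inter, config=config,
                           lasso_alpha=alpha)


# ---------------------------------------------------------------------------
# The signature
# ---------------------------------------------------------------------------

@dataclass
class SignatureModel:
    """Linear risk score over selected spatial features.

    ``score = Σ coefficient × z(feature)``, where the z-transform (and the
    median imputation for missing features) was fitted on the training split.
    A model built from bare coefficients (no preprocessor) scores raw values
    directly.
    """

    features: list[str]
    coefficients: np.ndarray
    cutoff: float | None = None
    preprocessor: Preprocessor | None = None
    training_summary: pd.DataFrame | None = field(repr=False, default=None)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.features) != len(self.coefficients):
            raise ValueError("features and coefficients must align")

    def score(self, X: pd.DataFrame) -> pd.Series:
        """SIS scores for a feature matrix (imputing and scaling as trained)."""
        if self.preprocessor is not None:
            Z = self.preprocessor.transform(X[self.features]
                                            if set(self.features) <= set(X.columns)
                                            else X)
            Z = Z[self.features]
        else:
            missing = [f for f in self.features if f not in X.columns]
            if missing:
                raise ValueError(f"feature(s) missing and no imputation available: {missing}")
            Z = X[self.features]
            if Z.isna().any().any():
                raise ValueError("missing feature values and no imputation available")
        return pd.Series(Z.to_numpy(dtype=float) @ self.coefficients,
                         index=X.index, name="sis")

    def to_json(self) -> str:
        payload = {
            "features": self.features,
            "coefficients": self.coefficients.tolist(),
            "cutoff": self.cutoff,
            "meta": self.meta,
        }
        if self.preprocessor is not None:
            payload["preprocessor"] = {
                "medians": self.preprocessor.medians[self.features].tolist(),
                "means": self.preprocessor.means[self.features].tolist(),
                "stds": self.preprocessor.stds[self.features].tolist(),
            }
        if self.training_summary is not None:
            payload["training_summary"] = json.loads(
                self.training_summary.to_json(orient="index"))
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        payload = json.loads(text)
        pre = None
        if "preprocessor" in payload:
            idx = pd.Index(payload["features"])
            pre = Preprocessor(
                medians=pd.Series(payload["preprocessor"]["medians"], index=idx),
                means=pd.Series(payload["preprocessor"]["means"], index=idx),
                stds=pd.Series(payload["preprocessor"]["stds"], index=idx),
            )
        return cls(features=payload["features"],
                   coefficients=np.asarray(payload["coefficients"]),
                   cutoff=payload.get("cutoff"), preprocessor=pre,
                   meta=payload.get("meta", {}))


def fit_signature(X: pd.DataFrame, times, events,
                  features: Sequence[str],
                  min_group_frac: float = 0.1,
                  meta: Mapping | None = None) -> SignatureModel:
    """Fit the SIS: multivariate Cox coefficients on the training split plus
    the optimal cutpoint of the resulting training scores."""
    features = list(features)
    if not features:
        raise ValueError("no features selected; cannot fit a signature")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if int(e.sum()) < 10:
        raise ValueError(f"need at least 10 events to fit the signature, got {int(e.sum())}")
    pre = Preprocessor.fit(X[features])
    Z = pre.transform(X[features])
    fit = cox_fit(Z, t, e)
    coefs = fit.coefficients[features].to_numpy()
    model = SignatureModel(features=features, coefficients=coefs,
                           preprocessor=pre, training_summary=fit.summary,
                           meta=dict(meta or {}))
    scores = model.score(X)
    model.cutoff = optimal_cutpoint(scores.to_numpy(), t, e,
                                    min_group_frac=min_group_frac).cutoff
    return model


def score_sis(values, model: SignatureModel) -> float:
    """Score one feature vector with a signature model.

    ``values`` may be a mapping/Series keyed by feature name or a plain
    sequence ordered like ``model.features``.  Missing entries are imputed
    from the model's stored training medians when available.
    """
    if isinstance(values, Mapping) or isinstance(values, pd.Series):
        row = pd.Series(values, dtype=float)
        v = row.reindex(model.features)
    else:
        arr = np.asarray(values, dtype=float)
        if arr.shape != (len(model.features),):
            raise ValueError(f"expected {len(model.features)} values, got {arr.shape}")
        v = pd.Series(arr, index=model.features)
    if v.isna().any():
        if model.preprocessor is None:
            raise ValueError(f"missing feature value(s) {list(v.index[v.isna()])} "
                             "and no imputation available")
        v = v.fillna(model.preprocessor.medians)
    if model.preprocessor is not None:
        v = (v - model.preprocessor.means) / model.preprocessor.stds
    return float(v.to_numpy() @ model.coefficients)
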