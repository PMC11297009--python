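"""Per-patient feature vectors from per-core spatial metrics.

Canonical feature names follow the grammar
``{D|N|P}({source}[_to_{target}])@{IM|TC}``, e.g. ``N(CD4Treg_to_Tumor)@IM``
or ``D(CD8Treg)@TC``.  When a patient contributes more than one core per
(region, panel) the defined per-core values are averaged with equal weight.
Undefined metrics (empty denominator sets — e.g. a core with no CD8+ Tregs
has no mNND from them) stay missing in the matrix; imputation happens only at
the model-fitting boundary, never in the stored table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FEATURE_NAME_RE = re.compile(
    r"^(?P<metric>[DNP])\((?P<source>[A-Za-z0-9]+)(_to_(?P<target>[A-Za-z0-9]+))?\)"
    r"@(?P<region>IM|TC)$")


def feature_name(metric: str, source: str, target: str | None, region: str) -> str:
    if metric == "D" or not target:
        return f"D({source})@{region}"
    return f"{metric}({source}_to_{target})@{region}"


def parse_feature_name(name: str) -> dict:
    m = FEATURE_NAME_RE.match(name)
    if m is None:
        raise ValueError(f"feature name {name!r} does not match the canonical grammar")
    return m.groupdict()


def build_feature_matrix(metrics: pd.DataFrame,
                         patients: pd.DataFrame | None = None) -> pd.DataFrame:
    """Pivot a long-format metric table into a patient × feature matrix.

    Parameters
    ----------
    metrics : DataFrame
        Long table as produced by :func:`spatsig.spatial_metrics.metrics_table`.
    patients : DataFrame, optional
        If given, patients without any core are reported (and excluded) by a
        logged warning; the matrix keeps only patients with cores.
    """
    if len(metrics) == 0:
        raise ValueError("empty metric table")
    tab = metrics.copy()
    tab["feature"] = [
        feature_name(m, s, t if isinstance(t, str) and t else None, r)
        for m, s, t, r in zip(tab["metric"], tab["source"], tab["target"], tab["region"])
    ]
    defined = tab.loc[tab["defined"].astype(bool)]
    wide = defined.pivot_table(index="patient_id", columns="feature",
                               values="value", aggfunc="mean")
    # patients (rows) and features (columns) that were measured but always
    # undefined still appear — as missing values, never zeros
    wide = wide.reindex(index=sorted(tab["patient_id"].unique()),
                        columns=sorted(tab["feature"].unique()))
    wide.columns.name = None
    if patients is not None:
        missing = set(patients["patient_id"]) - set(wide.index)
        if missing:
            logger.warning("excluding %d patient(s) with zero cores: %s",
                           len(missing), sorted(missing)[:5])
    return wide


@dataclass(frozen=True)
class GroupComparison:
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided Mann–Whitney U comparison of two groups.

    Uses the normal approximation with tie correction (no continuity
    correction); the reported U statistic is for the first group.
    """
    a = np.asarray(pd.Series(values_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(values_b).dropna(), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    return GroupComparison(u_statistic=float(res.statistic),
                           p_value=float(res.pvalue), n_a=len(a), n_b=len(b))


@dataclass(frozen=True)
class Dichotomy:
    labels: pd.Series          # "high" / "low"; NaN input -> NaN label
    cutoff: float
    policy: str


def dichotomize_feature(values, times=None, events=None, policy: str = "xtile",
                        min_group_frac: float = 0.1,
                        min_n: int = 20) -> Dichotomy:
    """Split patients into high/low groups on one feature.

    ``policy="median"`` cuts at the median of the defined values;
    ``policy="xtile"`` chooses the outcome-driven optimal cutpoint (log-rank
    maximization, see :func:`spatsig.survival_stats.optimal_cutpoint`) and
    therefore needs survival times and event indicators.
    """
    v = pd.Series(values, dtype=float)
    defined = v.dropna()
    if len(defined) < min_n:
        raise ValueError(f"need at least {min_n} defined values, got {len(defined)}")
    if defined.nunique() < 2:
        raise ValueError("feature is constant; no admissible cutoff")
    if policy == "median":
        cutoff = float(np.median(defined))
    elif policy == "xtile":
        if times is None or events is None:
            raise ValueError("xtile policy requires survival times and events")
        from .survival_stats import optimal_cutpoint
        mask = v.notna().to_numpy()
        cp = optimal_cutpoint(defined.to_numpy(),
                              np.asarray(times, dtype=float)[mask],
                              np.asarray(events, dtype=int)[mask],
                              min_group_frac=min_group_frac)
        cutoff = cp.cutoff
    else:
        raise ValueError(f"unknown policy {policy!r}")
    labels = pd.Series(np.where(v > cutoff, "high", "low"), index=v.index, dtype=object)
    labels[v.isna()] = np.nan
    return Dichotomy(labels=labels, cutoff=cutoff, policy=policy)


@dataclass
class Preprocessor:
    """Median imputation + z-scoring fitted on the training split only.

    Applying training-split statistics to validation data is the leakage
    guard for every downstream model fit; the stored feature matrix itself is
    never imputed.
    """

    medians: pd.Series
    means: pd.Series
    stds: pd.Series

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Preprocessor":
        if len(X.columns) == 0:
            raise ValueError("no features to preprocess")
        all_missing = X.columns[X.isna().all()]
        if len(all_missing):
            raise ValueError(f"feature(s) entirely missing in training data: "
                             f"{list(all_missing)[:5]}")
        medians = X.median()
        imputed = X.fillna(medians)
        means = imputed.mean()
        stds = imputed.std(ddof=0).replace(0.0, 1.0)
        return cls(medians=medians, means=means, stds=stds)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = X.reindex(columns=self.medians.index)
        return (X.fillna(self.medians) - self.means) / self.stds
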