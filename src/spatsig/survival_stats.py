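"""Survival machinery: Kaplan–Meier, log-rank, Cox PH, cutpoint search, time-dependent AUC.

Thin, validated wrappers around lifelines (product-limit estimator, log-rank
test, proportional-hazards fit with Efron tie handling) and scikit-survival
(Uno-type inverse-probability-of-censoring-weighted cumulative/dynamic AUC),
plus an outcome-driven optimal-cutpoint search in the style of X-tile:
scan all admissible midpoints between consecutive score values and keep the
one maximizing the two-group log-rank chi-square.  The p-value at the chosen
cutpoint is not corrected for the scan and is therefore optimistic; treat it
as descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv


def _check_times(times) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if not np.isfinite(t).all() or (t < 0).any():
        raise ValueError("survival times must be finite and non-negative")
    return t


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve.

    ``median`` is the earliest event time with S <= 0.5, or ``None`` when the
    curve never reaches 0.5 ("not reached").
    """

    times: np.ndarray           # distinct event times (drops of the curve)
    survival: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier estimate; tied deaths at a time enter one multiplication."""
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table
    drops = tab[tab["observed"] > 0]
    med = kmf.median_survival_time_
    surv = kmf.survival_function_["KM_estimate"]
    return KMCurve(
        times=drops.index.to_numpy(dtype=float),
        survival=surv.loc[drops.index].to_numpy(dtype=float),
        at_risk=drops["at_risk"].to_numpy(dtype=int),
        n_events=drops["observed"].to_numpy(dtype=int),
        median=None if np.isinf(med) else float(med),
    )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p_value: float
    df: int


def logrank(times, events, groups) -> LogrankResult:
    """K-sample log-rank test (observed − expected with hypergeometric variance)."""
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two non-empty groups")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(chi_square=float(res.test_statistic),
                         p_value=float(res.p_value), df=len(labels) - 1)


def _two_group_logrank_chi2(times: np.ndarray, events: np.ndarray,
                            in_high: np.ndarray) -> float:
    """Fast two-group log-rank chi-square (no object overhead), for cutpoint scans."""
    order = np.argsort(times, kind="stable")
    t, e, hi = times[order], events[order], in_high[order].astype(int)
    n = len(t)
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    # counts at risk just before each event time
    n_total = n
    n_high = int(hi.sum())
    ptr = 0
    for et in event_times:
        while ptr < n and t[ptr] < et:
            n_total -= 1
            n_high -= hi[ptr]
            ptr += 1
        at = np.flatnonzero(t == et)
        d = int(e[at].sum())
        d_high = int((e[at] * hi[at]).sum())
        if n_total <= 1 or d == 0:
            continue
        frac = n_high / n_total
        o_minus_e += d_high - d * frac
        var += d * frac * (1 - frac) * (n_total - d) / (n_total - 1)
    if var <= 0:
        return 0.0
    return o_minus_e * o_minus_e / var


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """Multivariate proportional-hazards fit (partial likelihood, Efron ties)."""

    coefficients: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p_values: pd.Series
    n: int
    n_events: int
    log_likelihood: float
    summary: pd.DataFrame = field(repr=False, default=None)
    fitter: CoxPHFitter = field(repr=False, default=None)

    def confidence_interval(self, term: str) -> tuple[float, float]:
        return float(self.ci_lower[term]), float(self.ci_upper[term])


def cox_fit(X: pd.DataFrame, times, events) -> CoxFit:
    """Fit a Cox model of the columns of ``X`` on right-censored outcomes."""
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    X = pd.DataFrame(X).reset_index(drop=True)
    if int(e.sum()) < X.shape[1] + 1:
        raise ValueError(
            f"need at least {X.shape[1] + 1} events for {X.shape[1]} covariate(s), "
            f"got {int(e.sum())}")
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"covariate(s) with no variation: {const}")
    df = X.copy()
    df["_time"] = t
    df["_event"] = e
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    s = cph.summary
    return CoxFit(
        coefficients=s["coef"],
        hazard_ratios=s["exp(coef)"],
        ci_lower=np.exp(s["coef lower 95%"]),
        ci_upper=np.exp(s["coef upper 95%"]),
        p_values=s["p"],
        n=len(df),
        n_events=int(e.sum()),
        log_likelihood=float(cph.log_likelihood_),
        summary=s,
        fitter=cph,
    )


# ---------------------------------------------------------------------------
# Optimal cutpoint (X-tile style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    chi_square: float
    p_value: float              # uncorrected for the scan; optimistic
    n_high: int
    n_low: int


def optimal_cutpoint(score, times, events, min_group_frac: float = 0.1) -> CutpointResult:
    """Outcome-driven dichotomization threshold.

    Scans the midpoints between consecutive distinct score values that leave
    at least ``min_group_frac`` of subjects in each arm and returns the one
    maximizing the two-group log-rank chi-square; ties go to the more
    balanced split.
    """
    s = np.asarray(score, dtype=float)
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    if len(s) != len(t):
        raise ValueError("score and survival arrays must align")
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValueError("score is constant; no admissible cutoff")
    n = len(s)
    min_arm = int(np.ceil(min_group_frac * n))
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for cut in candidates:
        hi = s > cut
        n_hi = int(hi.sum())
        if n_hi < min_arm or (n - n_hi) < min_arm:
            continue
        chi2 = _two_group_logrank_chi2(t, e, hi)
        balance = abs(n - 2 * n_hi)
        key = (-chi2, balance)
        if best is None or key < best[0]:
            best = (key, cut, chi2, n_hi)
    if best is None:
        raise ValueError("no admissible cutoff under the group-size constraint")
    _, cut, chi2, n_hi = best
    return CutpointResult(cutoff=float(cut), chi_square=float(chi2),
                          p_value=float(stats.chi2.sf(chi2, df=1)),
                          n_high=n_hi, n_low=n - n_hi)


# ---------------------------------------------------------------------------
# Time-dependent ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeROC:
    horizon: float
    auc: float
    weighting: str = "uno-ipcw"


def time_dependent_auc(score, times, events, horizon: float,
                       censor_times=None, censor_events=None) -> TimeROC:
    """Cumulative-case / dynamic-control AUC at ``horizon`` months.

    Inverse-probability-of-censoring weights come from the Kaplan–Meier
    estimate of the censoring distribution on ``censor_times`` /
    ``censor_events`` (defaults to the evaluated sample itself).
    """
    s = np.asarray(score, dtype=float)
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    if not ((t <= horizon) & (e == 1)).any():
        raise ValueError(f"no events observed before horizon {horizon}")
    if not (t > horizon).any():
        raise ValueError(f"no subjects at risk beyond horizon {horizon}")
    if censor_times is None:
        censor_times, censor_events = t, e
    y_train = Surv.from_arrays(np.asarray(censor_events, dtype=bool),
                               np.asarray(censor_times, dtype=float))
    y_test = Surv.from_arrays(e.astype(bool), t)
    auc, _ = cumulative_dynamic_auc(y_train, y_test, s, [horizon])
    return TimeROC(horizon=float(horizon), auc=float(auc[0]))
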