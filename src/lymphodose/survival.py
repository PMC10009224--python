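"""Survival analysis: Kaplan–Meier, log-rank, and Cox regression.

Times are months from the first day of chemoradiation.  Cox models use the
Efron tie correction and a univariable screen (retain p < 0.05) is provided
as a helper for choosing multivariable entry terms.
Fits are delegated to lifelines behind this module's interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMEstimate",
    "SurvivalFit",
    "km_estimate",
    "logrank",
    "cox_fit",
    "univariable_screen",
]


@dataclass
class KMEstimate:
    """Product-limit survival curve with right-continuous step lookup."""

    timeline: np.ndarray
    survival: np.ndarray
    median: float  # inf when the curve never crosses 0.5
    n: int
    n_events: int

    def survival_at(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        out = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(out) if out.ndim == 0 else out


def _check_times(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if not set(np.unique(events)) <= {0.0, 1.0}:
        raise ValueError("events must be 0/1")
    return times, events


def km_estimate(times, events) -> KMEstimate:
    """Kaplan–Meier product-limit estimate."""
    times, events = _check_times(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return KMEstimate(
        timeline=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(),
        median=float(kmf.median_survival_time_),
        n=times.size,
        n_events=int(events.sum()),
    )


def logrank(groups) -> tuple:
    """Log-rank test across >= 2 groups of (times, events).

    Returns (chi-square statistic, p-value, degrees of freedom).
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    times, events, labels = [], [], []
    for g, (t, e) in enumerate(groups):
        t, e = _check_times(t, e)
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, g))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return float(res.test_statistic), float(res.p_value), len(groups) - 1


@dataclass
class SurvivalFit:
    """Cox proportional-hazards fit summary (Efron ties)."""

    terms: list
    coef: pd.Series
    hazard_ratios: pd.Series
    conf_int: pd.DataFrame  # 95% CI on the HR scale, columns [lower, upper]
    pvalues: pd.Series
    n: int
    n_events: int
    loglik: float
    convergence_warning: bool = False


def cox_fit(times, events, covariates: pd.DataFrame) -> SurvivalFit:
    """Cox partial-likelihood fit with Wald intervals.

    Zero-variance covariates raise an error naming the column; separation /
    monotone-likelihood problems are flagged, not silently returned.
    """
    times, events = _check_times(times, events)
    if events.sum() == 0:
        raise ValueError("no events observed")
    X = pd.DataFrame(covariates).reset_index(drop=True)
    for col in X.columns:
        if float(X[col].std(ddof=0)) == 0.0:
            raise ValueError(f"covariate {col!r} has zero variance")
    df = X.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except ConvergenceError as err:
            raise ValueError(f"Cox fit failed to converge: {err}") from None
        flagged = any(
            "converg" in str(w.message).lower() or "collinear" in str(w.message).lower()
            for w in caught
        )
    summ = cph.summary
    terms = list(X.columns)
    return SurvivalFit(
        terms=terms,
        coef=summ["coef"].copy(),
        hazard_ratios=summ["exp(coef)"].copy(),
        conf_int=pd.DataFrame(
            {
                "lower": summ["exp(coef) lower 95%"],
                "upper": summ["exp(coef) upper 95%"],
            }
        ),
        pvalues=summ["p"].copy(),
        n=times.size,
        n_events=int(events.sum()),
        loglik=float(cph.log_likelihood_),
        convergence_warning=flagged,
    )


def univariable_screen(times, events, covariates: pd.DataFrame, alpha: float = 0.05) -> list:
    """Terms with univariable Cox p < alpha (candidate multivariable entries)."""
    keep = []
    for col in pd.DataFrame(covariates).columns:
        fit = cox_fit(times, events, pd.DataFrame(covariates)[[col]])
        if float(fit.pvalues.iloc[0]) < alpha:
            keep.append(col)
    return keep
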