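"""SRIL classification and risk modelling.

Severe radiation-induced lymphopenia (SRIL) is defined as two or more weekly
events of absolute lymphocyte count (ALC) strictly below 200 cells/µL
(CTCAE grade 4) during the chemoradiation course.  The modelling toolkit
covers: multivariable logistic regression (Wald intervals, AIC), per-fold
stepwise-AIC variable selection under ten-fold cross-validation with
majority-vote retention, maximally selected rank statistics for optimal
cutpoints of continuous dose metrics, AIC-based model comparison, and the
dose–response curve implied by a fitted logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SRILLabel",
    "LogisticFit",
    "CutpointResult",
    "classify_sril",
    "lymphopenia_grade",
    "fit_logistic",
    "stepwise_cv_select",
    "maxstat_cutpoint",
    "compare_aic",
    "dose_response",
]

GRADE4_ALC = 200.0  # cells/µL, CTCAE v5 grade-4 lymphopenia threshold
SRIL_MIN_EVENTS = 2


@dataclass(frozen=True)
class SRILLabel:
    n_grade4_events: int
    sril: bool

    def __post_init__(self):
        if self.sril != (self.n_grade4_events >= SRIL_MIN_EVENTS):
            raise ValueError("sril flag inconsistent with event count")


def classify_sril(weekly_alc) -> SRILLabel:
    """Count grade-4 weeks (ALC < 200/µL, strict) and flag SRIL at >= 2.

    Missing weeks (NaN) are skipped and never counted.  An all-missing series
    is an error, mirroring the exclusion of patients without weekly counts.
    """
    alc = np.asarray(weekly_alc, dtype=float)
    obs = alc[~np.isnan(alc)]
    if obs.size == 0:
        raise ValueError("no observed weekly ALC values")
    n = int(np.sum(obs < GRADE4_ALC))
    return SRILLabel(n_grade4_events=n, sril=n >= SRIL_MIN_EVENTS)


def lymphopenia_grade(alc: float, lln: float = 1000.0) -> int:
    """CTCAE-style lymphopenia grade for one ALC value (cells/µL).

    The grade-4 boundary (< 200) is the one the SRIL rule uses; the grade
    1–3 boundaries (< lln, < 800, < 500) are conventional defaults.
    """
    if np.isnan(alc):
        raise ValueError("cannot grade a missing ALC value")
    if alc < 200:
        return 4
    if alc < 500:
        return 3
    if alc < 800:
        return 2
    if alc < lln:
        return 1
    return 0


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression summary."""

    terms: list
    coef: pd.Series  # log-odds, including "intercept"
    odds_ratios: pd.Series
    conf_int: pd.DataFrame  # Wald 95% CI on the OR scale, columns [lower, upper]
    pvalues: pd.Series
    aic: float
    n: int
    loglik: float
    separation_warning: bool = False
    covariate_means: pd.Series = field(default=None, repr=False)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.coef["intercept"] + X[self.terms].to_numpy() @ self.coef[
            self.terms
        ].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def fit_logistic(X: pd.DataFrame | None, y) -> LogisticFit:
    """Fit a logistic model by IRLS with Wald intervals and AIC.

    ``X`` may be ``None`` or empty for the intercept-only null model.  Rank
    deficiency raises an error naming the collinear columns; (quasi-)complete
    separation is flagged on the result rather than silently diverging.
    """
    y = np.asarray(y, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        X = pd.DataFrame(index=pd.RangeIndex(len(y)))
    X = pd.DataFrame(X).reset_index(drop=True)
    terms = list(X.columns)
    if len(y) <= len(terms) + 1:
        raise ValueError("need more observations than model terms")
    design = sm.add_constant(X, has_constant="add") if terms else pd.DataFrame(
        {"const": np.ones(len(y))}
    )
    if terms:
        rank = np.linalg.matrix_rank(design.to_numpy())
        if rank < design.shape[1]:
            corr = X.corr().abs()
            np.fill_diagonal(corr.values, 0.0)
            collinear = sorted(set(corr.stack().idxmax())) if len(terms) > 1 else terms
            raise ValueError(f"rank-deficient design; collinear terms: {collinear}")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=100)
        except np.linalg.LinAlgError:
            # (quasi-)separation can make the IRLS Hessian singular; a
            # gradient-based fit still yields a usable, flagged result
            res = sm.Logit(y, design).fit(disp=0, maxiter=500, method="bfgs")
            separation = True
        separation |= any("separation" in str(w.message).lower() for w in caught)
    with np.errstate(invalid="ignore", over="ignore"):
        se = np.asarray(res.bse)
    if not res.mle_retvals.get("converged", True) or np.any(~np.isfinite(se)) or np.any(se > 50):
        separation = True
    names = ["intercept"] + terms
    coef = pd.Series(np.asarray(res.params), index=names)
    ci = res.conf_int()
    ci_arr = np.asarray(ci)
    return LogisticFit(
        terms=terms,
        coef=coef,
        odds_ratios=np.exp(coef),
        conf_int=pd.DataFrame(np.exp(ci_arr), index=names, columns=["lower", "upper"]),
        pvalues=pd.Series(np.asarray(res.pvalues), index=names),
        aic=float(res.aic),
        n=len(y),
        loglik=float(res.llf),
        separation_warning=separation,
        covariate_means=X.mean() if terms else pd.Series(dtype=float),
    )


def _stepwise_aic(X: pd.DataFrame, y, base_terms, candidates):
    """Bidirectional stepwise search minimising AIC from the base model."""
    current = list(base_terms)
    best_aic = fit_logistic(X[current] if current else None, y).aic
    while True:
        moves = []
        for c in candidates:
            if c not in current:
                moves.append((current + [c], f"+{c}"))
        for t in current:
            if t not in base_terms:
                moves.append(([u for u in current if u != t], f"-{t}"))
        improved = False
        for terms, _ in moves:
            aic = fit_logistic(X[terms] if terms else None, y).aic
            if aic < best_aic - 1e-9:
                best_aic, current, improved = aic, terms, True
        if not improved:
            return current


def stepwise_cv_select(
    X: pd.DataFrame,
    y,
    candidates,
    base_terms=(),
    folds: int = 10,
    seed=0,
) -> list:
    """Candidates retained by stepwise-AIC in a majority of CV folds.

    Fold assignment is a seeded permutation; within each fold's training
    portion a bidirectional stepwise-AIC search runs from the base model, and
    a candidate is selected when retained in more than ``folds/2`` folds.
    """
    y = np.asarray(y, dtype=float)
    candidates = list(candidates)
    base_terms = list(base_terms)
    if set(candidates) & set(base_terms):
        raise ValueError("candidates must be disjoint from base_terms")
    if not candidates:
        return base_terms
    if y.sum() < folds:
        raise ValueError(
            f"only {int(y.sum())} events for {folds} folds; use fewer folds"
        )
    rng = np.random.default_rng(seed)
    assign = rng.permutation(len(y)) % folds
    votes = {c: 0 for c in candidates}
    for f in range(folds):
        train = assign != f
        kept = _stepwise_aic(X.loc[train].reset_index(drop=True), y[train], base_terms, candidates)
        for c in candidates:
            if c in kept:
                votes[c] += 1
    return base_terms + [c for c in candidates if votes[c] > folds / 2]


@dataclass(frozen=True)
class CutpointResult:
    variable: str
    cutpoint: float
    statistic: float
    search_range: tuple
    p_value: float | None = None

    def __post_init__(self):
        lo, hi = self.search_range
        if not lo <= self.cutpoint <= hi:
            raise ValueError("cutpoint outside the search range")


def _maxstat_scan(y_sorted: np.ndarray, m_lo: int, m_hi: int) -> np.ndarray:
    """Standardised |S - E[S]| / sd[S] for splits after positions m_lo..m_hi.

    S is the sum of outcome scores in the low group of size m; mean and
    variance follow the permutation (rank-statistic) null.
    """
    n = y_sorted.size
    ybar = y_sorted.mean()
    var_a = np.mean((y_sorted - ybar) ** 2)
    m = np.arange(m_lo, m_hi + 1)
    s = np.cumsum(y_sorted)[m - 1]
    mean = m * ybar
    var = m * (n - m) / (n - 1) * var_a
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(s - mean) / np.sqrt(var)


def maxstat_cutpoint(
    x,
    y,
    search_range=(0.10, 0.90),
    variable: str = "x",
    n_permutations: int = 0,
    seed=None,
) -> CutpointResult:
    """Optimal cutpoint by maximally selected rank statistics.

    Candidate cutpoints are the distinct values of ``x`` inside the inner
    quantile ``search_range``; for each, the standardised two-sample linear
    rank statistic compares outcome scores between {x <= mu} and {x > mu}
    (for a binary outcome the 0/1 scores are affinely equivalent to Wilcoxon
    midranks, so the standardised statistic is identical).  The returned
    cutpoint is the midpoint between the argmax value and the next distinct
    value; an optional permutation p-value resamples the outcome labels.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class")
    lo_q, hi_q = np.quantile(x, search_range)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    distinct = np.unique(xs)
    cand = distinct[(distinct >= lo_q) & (distinct <= hi_q) & (distinct < distinct[-1])]
    if cand.size < 2:
        raise ValueError("fewer than 2 distinct candidate values in the search range")
    m_of = np.searchsorted(xs, cand, side="right")
    stats = _maxstat_scan(ys, int(m_of[0]), int(m_of[-1]))
    stats_at = stats[m_of - m_of[0]]
    best = int(np.argmax(stats_at))
    mu = cand[best]
    nxt = distinct[np.searchsorted(distinct, mu) + 1]
    p_value = None
    if n_permutations:
        rng = np.random.default_rng(seed)
        obs = stats_at[best]
        hits = 0
        for _ in range(n_permutations):
            yp = rng.permutation(ys)
            if _maxstat_scan(yp, int(m_of[0]), int(m_of[-1])).max() >= obs - 1e-12:
                hits += 1
        p_value = (hits + 1) / (n_permutations + 1)
    return CutpointResult(
        variable=variable,
        cutpoint=float(0.5 * (mu + nxt)),
        statistic=float(stats_at[best]),
        search_range=(float(lo_q), float(nxt) if nxt > hi_q else float(hi_q)),
        p_value=p_value,
    )


def compare_aic(fits: list) -> tuple:
    """Rank logistic fits by AIC ascending; ties go to the smaller model.

    Returns (ranked list, best fit).  Fits must share the outcome sample.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits}
    if len(ns) > 1:
        raise ValueError(f"fits computed on different sample sizes: {sorted(ns)}")
    ranked = sorted(fits, key=lambda f: (f.aic, len(f.terms)))
    return ranked, ranked[0]


def dose_response(
    fit: LogisticFit,
    variable: str,
    grid,
    covariate_values: dict | None = None,
) -> pd.DataFrame:
    """SRIL probability vs one model variable, others held at fixed values.

    Covariates default to the fitted sample means; the curve is
    ``p(d) = logistic(b0 + b_d * d + sum_j b_j * x_j)``.
    """
    if variable not in fit.terms:
        raise ValueError(f"variable {variable!r} not in fitted terms {fit.terms}")
    grid = np.asarray(grid, dtype=float)
    fixed = dict(fit.covariate_means)
    fixed.update(covariate_values or {})
    eta = np.full(grid.shape, fit.coef["intercept"])
    for t in fit.terms:
        eta = eta + fit.coef[t] * (grid if t == variable else fixed[t])
    return pd.DataFrame({variable: grid, "probability": 1.0 / (1.0 + np.exp(-eta))})
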