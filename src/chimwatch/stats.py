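"""Statistical primitives for chimerism-based relapse analysis.

Everything here is implemented directly from the defining formulas rather
than delegated to a statistics library, so that each estimator can be
checked against brute-force oracles (pairwise AUC, hypergeometric
enumeration, label-permutation, coefficient-grid search) in the test
suite.  SciPy is used only for reference distributions (normal and
chi-square tail probabilities, the hypergeometric pmf) and midranks.

Conventions
-----------
* Classification direction: a *higher* score means *higher* relapse
  risk; the decision rule is "positive iff score >= threshold".
* All p-values are two-sided unless stated otherwise, and are reported
  without any multiple-testing adjustment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _spstats

__all__ = [
    "RocResult",
    "LogisticFit",
    "SurvivalCurve",
    "SurvivalPoint",
    "TestResult",
    "roc",
    "sens_spec_at",
    "logistic_fit",
    "km",
    "survival_at",
    "logrank",
    "fisher_exact",
    "chi2_test",
    "mann_whitney",
    "loess_fit",
    "pearson_r",
]

_Z975 = 1.959963984540054  # Phi^-1(0.975), for Wald / Greenwood 95% CIs


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


@dataclass
class RocResult:
    """ROC sweep of the rule "predict relapse iff score >= threshold".

    ``thresholds`` are the distinct observed scores in ascending order
    plus ``+inf`` (the "predict nothing" rule), so the (fpr, tpr)
    polyline runs from (1, 1) down to (0, 0).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_cutoff: float
    j_at_cutoff: float
    sensitivity_at_cutoff: float
    specificity_at_cutoff: float
    n_pos: int
    n_neg: int


def roc(scores, labels) -> RocResult:
    """ROC curve, trapezoidal AUC and the Youden-optimal cutoff.

    Parameters
    ----------
    scores : array-like of float
        Per-unit risk scores (e.g. %max recipient chimerism).
    labels : array-like of bool/int
        1 for units that experienced the event (relapse), 0 otherwise.

    Returns
    -------
    RocResult
        The Youden cutoff maximizes J = sensitivity + specificity - 1;
        exact ties in J are broken toward the smallest threshold, which
        favors sensitivity.

    Raises
    ------
    ValueError
        If only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc requires both classes present "
                         f"(n_pos={n_pos}, n_neg={n_neg})")

    thr = np.append(np.unique(s), np.inf)
    pos_sorted = np.sort(s[y])
    neg_sorted = np.sort(s[~y])
    # count of scores >= t via binary search on the sorted class arrays
    tp = n_pos - np.searchsorted(pos_sorted, thr, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, thr, side="left")
    tpr = tp / n_pos
    fpr = fp / n_neg

    # thresholds ascend => fpr descends from 1 to 0; negate the integral
    auc = float(-np.trapezoid(tpr, fpr))

    # select the Youden threshold in exact integer arithmetic
    # (J is proportional to tp * n_neg - fp * n_pos) so that exact
    # ties are broken by threshold order, not rounding noise
    j_int = tp.astype(np.int64) * n_neg - fp.astype(np.int64) * n_pos
    j = tpr - fpr
    best = int(np.argmax(j_int))  # first occurrence = smallest threshold
    cutoff = float(thr[best])
    return RocResult(
        thresholds=thr,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        youden_cutoff=cutoff,
        j_at_cutoff=float(j[best]),
        sensitivity_at_cutoff=float(tpr[best]),
        specificity_at_cutoff=float(1.0 - fpr[best]),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def sens_spec_at(scores, labels, cutoff: float) -> tuple[float, float]:
    """Sensitivity and specificity of "positive iff score >= cutoff"."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if y.sum() == 0 or (~y).sum() == 0:
        raise ValueError("both classes must be non-empty")
    sens = float(np.mean(s[y] >= cutoff))
    spec = float(np.mean(s[~y] < cutoff))
    return sens, spec


# ---------------------------------------------------------------------------
# Logistic regression (IRLS / Newton with step halving)
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic regression fit.

    Odds ratios are ``exp(coef)``; confidence intervals are Wald
    (symmetric on the log-odds scale), matching the shape of CIs in
    clinical tables.
    """

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray          # OR scale
    ci_upper: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_obs: int
    n_iter: int
    converged: bool
    separation: bool


class SeparationWarning(UserWarning):
    pass


def _log_lik(X, y, beta):
    eta = X @ beta
    # log(1+exp(eta)) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def logistic_fit(
    covariates,
    outcome,
    names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> LogisticFit:
    """Fit a logistic regression by iteratively reweighted least squares.

    An intercept column is prepended automatically.  Convergence is
    declared when the log-likelihood improves by less than ``tol``.
    Quasi-complete separation is flagged when coefficients diverge
    (any |beta| > 30 on the log-odds scale); estimates are still
    reported, with a warning.

    Raises
    ------
    ValueError
        If the design (with intercept) is rank deficient.
    RuntimeError
        On non-convergence without detected separation.
    """
    Xc = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Xc.shape[0] == 1 and Xc.shape[1] > 1 and np.asarray(outcome).size == Xc.shape[1]:
        Xc = Xc.T
    y = np.asarray(outcome, dtype=float).ravel()
    n = y.size
    X = np.column_stack([np.ones(n), Xc])
    p = X.shape[1]
    if names is None:
        names = [f"x{j}" for j in range(1, p)]
    names = ["intercept"] + list(names)
    if len(names) != p:
        raise ValueError("names length must match number of covariates")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix (with intercept) is rank deficient")

    beta = np.zeros(p)
    ll = _log_lik(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = X.T @ (X * w[:, None])
        grad = X.T @ (y - mu)
        try:
            delta = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving keeps the Newton ascent monotone
        step = 1.0
        new_ll = _log_lik(X, y, beta + delta)
        while new_ll < ll and step > 1e-10:
            step *= 0.5
            new_ll = _log_lik(X, y, beta + step * delta)
        beta = beta + step * delta
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    separation = bool(np.max(np.abs(beta)) > 30.0)
    if separation:
        warnings.warn(
            "possible quasi-complete separation: coefficients diverged; "
            "Wald statistics are unreliable",
            SeparationWarning,
            stacklevel=2,
        )
    elif not converged:
        raise RuntimeError("logistic_fit did not converge")

    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf)
    pvals = 2.0 * _spstats.norm.sf(np.abs(z))
    return LogisticFit(
        names=names,
        coef=beta,
        se=se,
        odds_ratios=np.exp(beta),
        ci_lower=np.exp(np.clip(beta - _Z975 * se, -700, 700)),
        ci_upper=np.exp(np.clip(beta + _Z975 * se, -700, 700)),
        p_values=pvals,
        log_likelihood=float(ll),
        n_obs=n,
        n_iter=it,
        converged=converged or separation,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    """Product-limit estimate with Greenwood 95% confidence bands.

    The grid holds distinct *event* times in ascending order; the curve
    is right-continuous and constant between events.  At a tied time,
    events are processed before censorings (a unit censored at t is
    still at risk at t).
    """

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_units: int
    max_time: float


@dataclass
class SurvivalPoint:
    time: float
    estimate: float
    ci_lower: float
    ci_upper: float
    extrapolated: bool


def km(times, events) -> SurvivalCurve:
    """Kaplan-Meier estimator of the survival (relapse-free) function."""
    t = np.asarray(times, dtype=float)
    d = np.asarray(events).astype(bool)
    if t.size == 0:
        raise ValueError("km requires at least one unit")
    if np.any(t < 0):
        raise ValueError("follow-up times must be non-negative")

    event_times = np.unique(t[d])
    surv = np.empty(event_times.size)
    lo = np.empty(event_times.size)
    hi = np.empty(event_times.size)
    at_risk = np.empty(event_times.size, dtype=int)
    n_ev = np.empty(event_times.size, dtype=int)

    s = 1.0
    gw = 0.0  # Greenwood cumulative sum of d / (n (n - d))
    for i, tau in enumerate(event_times):
        n_i = int(np.sum(t >= tau))
        d_i = int(np.sum(d & (t == tau)))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            gw += d_i / (n_i * (n_i - d_i))
            se = s * math.sqrt(gw)
        else:
            se = 0.0  # S hit zero; variance degenerates
        surv[i] = s
        lo[i] = min(max(s - _Z975 * se, 0.0), 1.0)
        hi[i] = min(max(s + _Z975 * se, 0.0), 1.0)
        at_risk[i] = n_i
        n_ev[i] = d_i

    return SurvivalCurve(
        times=event_times,
        survival=surv,
        ci_lower=lo,
        ci_upper=hi,
        n_at_risk=at_risk,
        n_events=n_ev,
        n_units=int(t.size),
        max_time=float(t.max()),
    )


def survival_at(curve: SurvivalCurve, t: float) -> SurvivalPoint:
    """Evaluate the right-continuous step function S(t) with its CI.

    Beyond the last observed follow-up time the last value is carried
    forward and flagged as extrapolated.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    extrapolated = t > curve.max_time
    idx = int(np.searchsorted(curve.times, t, side="right")) - 1
    if idx < 0:
        return SurvivalPoint(t, 1.0, 1.0, 1.0, extrapolated)
    return SurvivalPoint(
        t,
        float(curve.survival[idx]),
        float(curve.ci_lower[idx]),
        float(curve.ci_upper[idx]),
        extrapolated,
    )


@dataclass
class TestResult:
    """A named test statistic with its p-value."""

    name: str
    statistic: float
    p_value: float
    df: float | None = None
    note: str = ""


def logrank(times_a, events_a, times_b, events_b) -> TestResult:
    """Two-group log-rank test.

    Sums observed-minus-expected events for group A over the pooled
    distinct event times, with the hypergeometric variance at each
    time, and refers (O-E)^2 / V to chi-square with 1 df.
    """
    ta = np.asarray(times_a, dtype=float)
    da = np.asarray(events_a).astype(bool)
    tb = np.asarray(times_b, dtype=float)
    db = np.asarray(events_b).astype(bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")

    all_t = np.concatenate([ta, tb])
    all_d = np.concatenate([da, db])
    event_times = np.unique(all_t[all_d])
    if event_times.size == 0:
        warnings.warn("no events in either group; log-rank p set to 1",
                      stacklevel=2)
        return TestResult("log-rank", 0.0, 1.0, df=1)

    o_minus_e = 0.0
    var = 0.0
    for tau in event_times:
        n1 = int(np.sum(ta >= tau))
        n2 = int(np.sum(tb >= tau))
        n = n1 + n2
        d1 = int(np.sum(da & (ta == tau)))
        d2 = int(np.sum(db & (tb == tau)))
        dtot = d1 + d2
        if n1 == 0 or n2 == 0:
            continue
        e1 = dtot * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += dtot * (n1 / n) * (n2 / n) * (n - dtot) / (n - 1)
    if var == 0.0:
        return TestResult("log-rank", 0.0, 1.0, df=1,
                          note="zero variance (no informative event times)")
    stat = o_minus_e**2 / var
    return TestResult("log-rank", float(stat),
                      float(_spstats.chi2.sf(stat, 1)), df=1)


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table.

    The two-sided p-value is the sum of hypergeometric probabilities of
    all tables with the same margins whose point probability does not
    exceed that of the observed table (the point-probability method,
    the convention of most clinical software).
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer):
        tab_f = np.asarray(table, dtype=float)
        if np.any(tab_f < 0) or np.any(tab_f != np.round(tab_f)):
            raise ValueError("counts must be non-negative integers")
        tab = tab_f.astype(int)
    a, b = int(tab[0, 0]), int(tab[0, 1])
    c, d = int(tab[1, 0]), int(tab[1, 1])
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return TestResult("fisher-exact", 0.0, 1.0, note="empty table")
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _spstats.hypergeom.pmf(support, n, r1, c1)
    p_obs = float(_spstats.hypergeom.pmf(a, n, r1, c1))
    p = float(np.sum(pmf[pmf <= p_obs * (1.0 + 1e-7)]))
    return TestResult("fisher-exact", p_obs, min(p, 1.0))


def chi2_test(table) -> TestResult:
    """Pearson chi-square test of independence for an r x k table."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(tab < 0):
        raise ValueError("counts must be non-negative")
    rows = tab.sum(axis=1)
    cols = tab.sum(axis=0)
    n = tab.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal total")
    expected = np.outer(rows, cols) / n
    stat = float(np.sum((tab - expected) ** 2 / expected))
    dof = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    return TestResult("chi-square", stat, float(_spstats.chi2.sf(stat, dof)),
                      df=dof)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _mw_exact_dist(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the rank sum of sample 1 (no ties), by the
    generating-polynomial recurrence; returns counts indexed by U."""
    n = n1 + n2
    max_sum = n1 * n  # upper bound on rank sum
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    counts[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(n1, r), 0, -1):
            counts[k, r:] += counts[k - 1, :-r] if r > 0 else counts[k - 1]
    rank_sum_counts = counts[n1]
    offset = n1 * (n1 + 1) // 2  # U = R1 - n1(n1+1)/2
    return rank_sum_counts[offset:offset + n1 * n2 + 1]


def mann_whitney(x, y) -> TestResult:
    """Mann-Whitney U test (two-sided).

    U is computed from midrank sums.  For n1 + n2 <= 12 with no ties
    the p-value is exact (full null distribution via the rank-sum
    recurrence); otherwise a normal approximation with tie and
    continuity corrections is used.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    n1, n2 = xa.size, ya.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    ranks = _spstats.rankdata(pooled)  # midranks
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    has_ties = np.unique(pooled).size < n

    if n <= 12 and not has_ties:
        dist = _mw_exact_dist(n1, n2)
        total = dist.sum()
        u_int = int(round(u))
        u_lo = min(u_int, n1 * n2 - u_int)
        u_hi = n1 * n2 - u_lo
        if u_lo == u_hi:
            p = 1.0
        else:
            p = (dist[: u_lo + 1].sum() + dist[u_hi:].sum()) / total
        return TestResult("mann-whitney-U", u, float(min(p, 1.0)),
                          note="exact")

    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return TestResult("mann-whitney-U", u, 1.0,
                          note="degenerate (all values tied)")
    cc = 0.5 if u != mu else 0.0
    z = (u - mu - math.copysign(cc, u - mu)) / math.sqrt(var)
    p = 2.0 * _spstats.norm.sf(abs(z))
    return TestResult("mann-whitney-U", u, float(min(p, 1.0)),
                      note="normal approximation")


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------


def loess_fit(x, y, grid, span: float = 0.75, degree: int = 1) -> np.ndarray:
    """Locally weighted polynomial smoother (tricube weights).

    At each grid point, a degree-``degree`` polynomial is fit by
    weighted least squares to the nearest ``ceil(span * n)`` data
    points, with tricube weights in the scaled distance.

    Raises
    ------
    ValueError
        For an invalid span, too few points, or a degenerate local
        design (all x equal within a window).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    g = np.asarray(grid, dtype=float)
    n = xa.size
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    if n < degree + 2:
        raise ValueError(f"need at least degree + 2 = {degree + 2} points")

    k = min(n, max(int(math.ceil(span * n)), degree + 2))
    fitted = np.empty(g.size)
    for i, x0 in enumerate(g):
        dist = np.abs(xa - x0)
        idx = np.argpartition(dist, k - 1)[:k]
        d = dist[idx]
        dmax = d.max()
        if np.ptp(xa[idx]) == 0.0 and degree >= 1:
            raise ValueError("degenerate local design: all x equal in window")
        if dmax == 0.0:
            fitted[i] = float(ya[idx].mean())
            continue
        w = (1.0 - np.clip(d / dmax, 0.0, 1.0) ** 3) ** 3
        if np.count_nonzero(w) < degree + 1:
            # boundary windows can zero out too many weights; soften
            w = (1.0 - np.clip(d / (dmax * (1.0 + 1e-9)), 0.0, 1.0) ** 3) ** 3
        sw = np.sqrt(w)
        design = np.vander(xa[idx] - x0, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], ya[idx] * sw,
                                   rcond=None)
        fitted[i] = float(coef[0])
    return fitted


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient.

    Raises ``ValueError`` for n < 3 or zero variance in either
    coordinate (a degenerate correlation is an error, not a number).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("pearson_r requires n >= 3")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sx = float(np.sqrt(np.sum(dx * dx)))
    sy = float(np.sqrt(np.sum(dy * dy)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in one coordinate")
    return float(np.sum(dx * dy) / (sx * sy))
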