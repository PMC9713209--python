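"""Unit and oracle tests for the from-scratch statistics engine.

Each estimator is checked two ways where possible: against a
brute-force/closed-form oracle written independently here, and against
an established library (scipy / statsmodels / lifelines / sklearn) on
the same inputs.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy import stats as sps

from chimwatch import (
    chi2_test,
    fisher_exact,
    km,
    loess_fit,
    logistic_fit,
    logrank,
    mann_whitney,
    pearson_r,
    roc,
    sens_spec_at,
    survival_at,
)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


def auc_pairwise(scores, labels):
    """Oracle: mean over (pos, neg) pairs of 1/0.5/0 for >, =, <."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (pos.size * neg.size)


def test_roc_perfect_separation():
    scores = [0.1, 0.2, 2.0, 3.0]
    labels = [0, 0, 1, 1]
    res = roc(scores, labels)
    assert res.auc == 1.0
    assert res.youden_cutoff == 2.0
    assert res.j_at_cutoff == 1.0
    assert sens_spec_at(scores, labels, res.youden_cutoff) == (1.0, 1.0)


def test_roc_all_tied_scores_is_chance():
    res = roc([1.0] * 10, [0, 1] * 5)
    assert res.auc == pytest.approx(0.5, abs=1e-15)


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc([1.0, 2.0], [1, 1])


@pytest.mark.parametrize("trial", range(20))
def test_auc_matches_pairwise_oracle(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(6, 60))
    scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
    labels = rng.integers(0, 2, size=n)
    if labels.sum() in (0, n):
        labels[0] = 1 - labels[0]
    res = roc(scores, labels)
    assert res.auc == pytest.approx(auc_pairwise(scores, labels), abs=1e-12)


@pytest.mark.parametrize("trial", range(10))
def test_youden_matches_exhaustive_sweep(trial):
    rng = np.random.default_rng(100 + trial)
    scores = np.round(rng.normal(size=40), 1)
    labels = rng.integers(0, 2, size=40)
    if labels.sum() in (0, 40):
        labels[0] = 1 - labels[0]
    res = roc(scores, labels)
    from fractions import Fraction
    n_pos, n_neg = labels.sum(), (1 - labels).sum()
    best_j, best_t = Fraction(-2), None
    for t in sorted(np.unique(scores)):  # ascending => ties keep smallest
        sens = Fraction(int((scores[labels == 1] >= t).sum()), int(n_pos))
        spec = Fraction(int((scores[labels == 0] < t).sum()), int(n_neg))
        if sens + spec - 1 > best_j:
            best_j, best_t = sens + spec - 1, t
    assert res.youden_cutoff == best_t
    assert res.j_at_cutoff == pytest.approx(float(best_j), abs=1e-12)


def test_auc_agrees_with_sklearn(rng):
    from sklearn.metrics import roc_auc_score
    scores = rng.normal(size=80)
    labels = rng.integers(0, 2, size=80)
    labels[0], labels[1] = 0, 1
    assert roc(scores, labels).auc == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hst.integers(0, 2**32 - 1))
def test_auc_invariant_under_increasing_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=30)
    labels = rng.integers(0, 2, size=30)
    labels[:2] = [0, 1]
    a1 = roc(scores, labels).auc
    a2 = roc(np.exp(scores / 2.0), labels).auc  # strictly increasing map
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_sens_spec_extremes(rng):
    scores = rng.normal(size=20)
    labels = rng.integers(0, 2, size=20)
    labels[:2] = [0, 1]
    assert sens_spec_at(scores, labels, scores.min() - 1) == (1.0, 0.0)
    sens, spec = sens_spec_at(scores, labels, scores.max() + 1)
    assert (sens, spec) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# Logistic regression
# ---------------------------------------------------------------------------


def test_logistic_null_covariate_slope_zero(rng):
    x = np.concatenate([-np.arange(1, 21), np.arange(1, 21)])  # symmetric
    y = np.tile([0, 1], 20)  # outcome independent of x by symmetry
    fit = logistic_fit(x[:, None], y)
    assert abs(fit.coef[1]) < 1e-6


def test_logistic_2x2_equals_cross_product_ratio():
    # counts: exposed 12 events / 6 non-events, unexposed 11 / 58
    a, b, c, d = 12, 6, 11, 58
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    fit = logistic_fit(x[:, None], y)
    assert fit.odds_ratios[1] == pytest.approx((a * d) / (b * c), rel=1e-8)


def test_logistic_score_equations_hold(rng):
    x = rng.normal(size=(50, 2))
    y = (rng.random(50) < 1 / (1 + np.exp(-(0.5 + x @ [1.0, -0.7])))).astype(float)
    fit = logistic_fit(x, y)
    X = np.column_stack([np.ones(50), x])
    p = 1 / (1 + np.exp(-(X @ fit.coef)))
    score = X.T @ (y - p)
    assert np.max(np.abs(score)) < 1e-8


def test_logistic_beats_surrounding_grid(rng):
    x = rng.normal(size=20)
    y = rng.integers(0, 2, size=20).astype(float)
    y[:2] = [0, 1]
    fit = logistic_fit(x[:, None], y)

    def ll(beta):
        eta = beta[0] + beta[1] * x
        return float(y @ eta - np.logaddexp(0, eta).sum())

    b0, b1 = fit.coef
    for d0 in np.linspace(-0.5, 0.5, 7):
        for d1 in np.linspace(-0.5, 0.5, 7):
            assert fit.log_likelihood >= ll([b0 + d0, b1 + d1]) - 1e-9


def test_logistic_matches_statsmodels(rng):
    import statsmodels.api as sm
    x = rng.normal(size=(60, 2))
    y = (rng.random(60) < 0.4).astype(float)
    y[:2] = [0, 1]
    fit = logistic_fit(x, y)
    ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
    np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, rtol=1e-4)
    np.testing.assert_allclose(fit.p_values, ref.pvalues, atol=1e-6)


def test_logistic_separation_flagged():
    x = np.array([0, 1, 2, 3, 10, 11, 12, 13], float)
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
    with pytest.warns(UserWarning, match="separation"):
        fit = logistic_fit(x[:, None], y)
    assert fit.separation


def test_logistic_rank_deficient_errors(rng):
    x = rng.normal(size=30)
    X = np.column_stack([x, 2 * x])
    y = (rng.random(30) < 0.5).astype(float)
    with pytest.raises(ValueError, match="rank"):
        logistic_fit(X, y)


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------


def test_km_no_events_flat():
    curve = km([10, 20, 30], [0, 0, 0])
    assert curve.times.size == 0
    assert survival_at(curve, 25).estimate == 1.0


def test_km_hand_product_limit_with_censoring():
    # times {5, 10, 15}, events {1, 0, 1}: S(5)=2/3; at t=15 the risk
    # set is the single unit left after the censoring at 10, so S=0
    curve = km([5, 10, 15], [1, 0, 1])
    np.testing.assert_allclose(curve.times, [5, 15])
    assert survival_at(curve, 5).estimate == pytest.approx(2 / 3)
    assert survival_at(curve, 15).estimate == pytest.approx(0.0)
    assert survival_at(curve, 12).estimate == pytest.approx(2 / 3)


def test_km_all_events_is_one_minus_ecdf(rng):
    t = rng.permutation(np.arange(1.0, 11.0))
    curve = km(t, np.ones(10))
    for k, tau in enumerate(np.sort(t), start=1):
        assert survival_at(curve, tau).estimate == pytest.approx((10 - k) / 10)


def test_km_tied_event_and_censoring_event_first():
    # censored at 10 is still at risk for the event at 10
    curve = km([10, 10, 20], [1, 0, 1])
    assert survival_at(curve, 10).estimate == pytest.approx(2 / 3)


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter
    t = np.round(rng.exponential(100, size=60)) + 1
    e = rng.integers(0, 2, size=60)
    curve = km(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for tau in [10, 50, 120, 300]:
        assert survival_at(curve, tau).estimate == pytest.approx(
            float(kmf.predict(tau)), abs=1e-12)


def test_survival_at_extrapolation_flag():
    curve = km([5, 10], [1, 0])
    assert survival_at(curve, 0).estimate == 1.0
    pt = survival_at(curve, 100)
    assert pt.extrapolated


def test_logrank_identical_groups_null():
    t = [5, 10, 15, 20]
    e = [1, 0, 1, 1]
    res = logrank(t, e, t, e)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_hand_computed_fixture():
    # group A: events at 1, 2; group B: event at 3.
    # t=1: n=(2,1), d=1 -> E_A = 2/3, V = (2/3)(1/3)
    # t=2: n=(1,1), d=1 -> E_A = 1/2, V = 1/4
    # t=3: n=(0,1) -> skipped (one group empty)
    ta, ea = [1, 2], [1, 1]
    tb, eb = [3], [1]
    o_minus_e = (1 - 2 / 3) + (1 - 1 / 2)
    var = (2 / 3) * (1 / 3) + 1 / 4
    expected = o_minus_e**2 / var
    res = logrank(ta, ea, tb, eb)
    assert res.statistic == pytest.approx(expected, abs=1e-12)


def test_logrank_matches_lifelines(rng):
    from lifelines.statistics import logrank_test
    ta = np.round(rng.exponential(80, 40)) + 1
    ea = rng.integers(0, 2, 40)
    tb = np.round(rng.exponential(120, 50)) + 1
    eb = rng.integers(0, 2, 50)
    res = logrank(ta, ea, tb, eb)
    ref = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    assert res.statistic == pytest.approx(ref.test_statistic, rel=1e-10)
    assert res.p_value == pytest.approx(ref.p_value, rel=1e-10)


def test_logrank_no_events_warns():
    with pytest.warns(UserWarning, match="no events"):
        res = logrank([5, 6], [0, 0], [7], [0])
    assert res.p_value == 1.0


def test_logrank_null_p_approximately_uniform(rng):
    """Exchangeable groups: the permutation distribution of p should be
    roughly uniform (KS check over 500 label permutations)."""
    t = np.round(rng.exponential(100, 30)) + 1
    e = rng.integers(0, 2, 30)
    e[:5] = 1
    pvals = []
    for _ in range(500):
        perm = rng.permutation(30)
        ga, gb = perm[:15], perm[15:]
        pvals.append(logrank(t[ga], e[ga], t[gb], e[gb]).p_value)
    ks = sps.kstest(pvals, "uniform")
    assert ks.pvalue > 0.001


# ---------------------------------------------------------------------------
# Fisher / chi-square
# ---------------------------------------------------------------------------


def fisher_enumeration(table):
    """Oracle: full hypergeometric enumeration from factorials."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def table_prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_prob(a)
    return sum(p for k in range(lo, hi + 1)
               if (p := table_prob(k)) <= p_obs * (1 + 1e-7))


def test_fisher_two_table_case():
    assert fisher_exact([[1, 0], [0, 1]]).p_value == pytest.approx(1.0)


def test_fisher_adult_mortality_counts_highly_significant():
    # 12/18 deaths with relapse vs 11/69 without
    res = fisher_exact([[12, 6], [11, 58]])
    assert res.p_value < 0.0001


@pytest.mark.parametrize("trial", range(25))
def test_fisher_matches_enumeration_oracle(trial):
    rng = np.random.default_rng(trial)
    table = rng.integers(0, 15, size=(2, 2))
    p = fisher_exact(table).p_value
    assert p == pytest.approx(fisher_enumeration(table.tolist()), abs=1e-12)
    # scipy's two-sided convention is the same point-probability method
    assert p == pytest.approx(sps.fisher_exact(table)[1], abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(hst.lists(hst.integers(0, 20), min_size=4, max_size=4))
def test_fisher_invariant_under_transposition_and_swaps(cells):
    a, b, c, d = cells
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return
    base = fisher_exact([[a, b], [c, d]]).p_value
    assert fisher_exact([[a, c], [b, d]]).p_value == pytest.approx(base, abs=1e-12)
    assert fisher_exact([[c, d], [a, b]]).p_value == pytest.approx(base, abs=1e-12)
    assert fisher_exact([[b, a], [d, c]]).p_value == pytest.approx(base, abs=1e-12)


def test_fisher_rejects_negative_counts():
    with pytest.raises(ValueError):
        fisher_exact([[1, -2], [3, 4]])


def test_chi2_exact_independence_gives_zero():
    res = chi2_test([[10, 20, 30], [20, 40, 60]])
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_2x3_matches_direct_formula_and_scipy():
    table = np.array([[12, 7, 3], [5, 9, 14]], float)
    rows, cols, n = table.sum(1), table.sum(0), table.sum()
    expected = np.outer(rows, cols) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    res = chi2_test(table)
    assert res.statistic == pytest.approx(stat, abs=1e-12)
    assert res.df == 2
    ref = sps.chi2_contingency(table, correction=False)
    assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
    assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)


def test_chi2_mean_statistic_near_df_under_null(rng):
    stats = []
    for _ in range(300):
        counts = rng.multinomial(60, [1 / 6] * 6).reshape(2, 3)
        if (counts.sum(0) == 0).any() or (counts.sum(1) == 0).any():
            continue
        stats.append(chi2_test(counts).statistic)
    assert np.mean(stats) == pytest.approx(2.0, abs=0.35)


def test_chi2_zero_marginal_errors():
    with pytest.raises(ValueError, match="marginal"):
        chi2_test([[0, 0], [3, 4]])


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------


def mw_u(x, y):
    return sum(1.0 if xi > yi else (0.5 if xi == yi else 0.0)
               for xi in x for yi in y)


def mw_exact_two_sided(x, y):
    """Oracle: enumerate all label assignments of the pooled sample."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mw_u(x, y)
    u_lo = min(u_obs, len(x) * len(y) - u_obs)
    u_hi = len(x) * len(y) - u_lo
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = mw_u(xs, ys)
        total += 1
        if u <= u_lo + 1e-9 or u >= u_hi - 1e-9:
            count += 1
    return count / total


def test_mw_identical_samples_centered():
    res = mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.statistic == pytest.approx(4.5)  # n1*n2/2
    assert res.p_value == pytest.approx(1.0)


@pytest.mark.parametrize("trial", range(10))
def test_mw_exact_p_matches_enumeration(trial):
    rng = np.random.default_rng(trial)
    n1 = int(rng.integers(2, 6))
    n2 = int(rng.integers(2, 13 - n1))
    pooled = rng.permutation(np.arange(n1 + n2, dtype=float))  # no ties
    x, y = pooled[:n1], pooled[n1:]
    res = mann_whitney(x, y)
    assert res.note == "exact"
    assert res.p_value == pytest.approx(mw_exact_two_sided(x, y), abs=1e-12)


def test_mw_complete_separation_combinatorial_p():
    x = [10.0, 11.0, 12.0]
    y = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney(x, y)
    assert res.statistic == 12.0  # maximal U = n1*n2
    # two-sided: both extreme assignments out of C(7,3)
    assert res.p_value == pytest.approx(2 / math.comb(7, 3), abs=1e-12)


def test_mw_normal_approx_close_to_scipy(rng):
    x = rng.normal(size=25)
    y = rng.normal(0.5, size=30)
    res = mann_whitney(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------


def test_loess_reproduces_exact_line(rng):
    x = np.sort(rng.uniform(0, 10, 40))
    y = 2.0 * x - 3.0
    grid = np.linspace(0, 10, 15)
    fitted = loess_fit(x, y, grid, span=0.5, degree=1)
    np.testing.assert_allclose(fitted, 2.0 * grid - 3.0, atol=1e-10)


def test_loess_constant_y(rng):
    x = np.sort(rng.uniform(0, 5, 20))
    fitted = loess_fit(x, np.full(20, 7.0), np.linspace(0, 5, 9))
    np.testing.assert_allclose(fitted, 7.0, atol=1e-10)


def test_loess_full_span_matches_direct_wls(rng):
    x = np.sort(rng.uniform(0, 1, 12))
    y = rng.normal(size=12)
    x0 = x[5]
    fitted = loess_fit(x, y, [x0], span=1.0, degree=1)[0]
    d = np.abs(x - x0)
    w = (1 - (d / d.max()) ** 3) ** 3
    X = np.column_stack([np.ones(12), x - x0])
    beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
    assert fitted == pytest.approx(beta[0], abs=1e-10)


def test_loess_degenerate_window_errors():
    with pytest.raises(ValueError):
        loess_fit([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4], [1.0], span=1.0)


def test_loess_invalid_span():
    with pytest.raises(ValueError):
        loess_fit([1, 2, 3, 4], [1, 2, 3, 4], [2.0], span=1.5)


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------


def test_pearson_collinear():
    assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [-2, -4, -6]) == pytest.approx(-1.0)


def test_pearson_matches_formula_oracle(rng):
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    dx, dy = x - x.mean(), y - y.mean()
    expected = (dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum())
    assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_degenerate_errors():
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_r([1, 2], [3, 4])
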