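"""Kaplan-Meier, log-rank, Cox, cutpoint, tree, Fisher and ANOVA checks."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnsubtype import survival as sv
from cnsubtype.cn_core import CnError


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_hand_example():
    """Four deaths at 10/20/30/40: S is 0.75/0.5/0.25/0 stepwise."""
    c = sv.km_fit([10, 20, 30, 40], [1, 1, 1, 1])
    np.testing.assert_allclose(c.surv, [0.75, 0.5, 0.25, 0.0])
    s, lo, hi, _ = sv.survival_at(c, 25)
    assert s == 0.5
    # Greenwood log-scale CI at t=10: var(log S) = 1/(4*3)
    se = np.sqrt(1 / 12)
    assert c.ci_low[0] == pytest.approx(0.75 * np.exp(-sv.Z95 * se))
    assert c.ci_high[0] == pytest.approx(min(1.0, 0.75 * np.exp(sv.Z95 * se)))


def test_km_no_events_and_t0():
    c = sv.km_fit([5, 8, 12], [0, 0, 0])
    assert (c.surv == 1.0).all()
    assert sv.survival_at(c, 0)[0] == 1.0


def test_km_equals_empirical_survival_without_censoring(rng):
    t = rng.exponential(10, 200).round(1)  # ties included
    c = sv.km_fit(t, np.ones_like(t))
    for q in [1, 5, 10, 20]:
        assert sv.survival_at(c, q)[0] == pytest.approx((t > q).mean(), abs=1e-12)


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter

    t = rng.exponential(10, 150).round(0) + 1
    e = rng.integers(0, 2, 150)
    ours = sv.km_fit(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    theirs = kmf.survival_function_at_times(ours.times).to_numpy()
    np.testing.assert_allclose(ours.surv, theirs, atol=1e-10)


def test_km_truncation_time_records_10pct_at_risk():
    t = list(range(1, 21))
    c = sv.km_fit(t, [1] * 20)
    # after the death at t=19 only 1 of 20 (5%) remains at risk
    assert c.trunc_time == 19


def test_km_negative_times_error():
    with pytest.raises(CnError):
        sv.km_fit([-1, 2], [1, 1])


def test_survival_at_beyond_followup_flagged():
    c = sv.km_fit([10, 20], [1, 0])
    *_, beyond = sv.survival_at(c, 50)
    assert beyond


def test_km_monte_carlo_matches_exponential_closed_form(rng):
    lam = -np.log(0.615) / 60.0
    n = 20000
    t_event = rng.exponential(1 / lam, n)
    t_cens = rng.uniform(0, 120, n)
    c = sv.km_fit(np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int))
    assert sv.survival_at(c, 60)[0] == pytest.approx(0.615, abs=0.01)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    t = [3, 5, 7, 11, 13]
    e = [1, 0, 1, 1, 0]
    chi2, p, df = sv.logrank_test(t + t, e + e, ["a"] * 5 + ["b"] * 5)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)
    assert df == 1


def test_logrank_z_matches_lifelines(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    t = rng.exponential(10, 80)
    e = rng.integers(0, 2, 80)
    g = rng.integers(0, 2, 80).astype(bool)
    z = sv.logrank_z(t, e, g)
    res = ll_logrank(t[g], t[~g], e[g], e[~g])
    assert z**2 == pytest.approx(res.test_statistic, rel=1e-8)


def test_logrank_agrees_with_exhaustive_permutation():
    """Six subjects, all label assignments enumerated as the null oracle."""
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.array([1, 1, 1, 1, 1, 1])
    obs_group = np.array([True, True, True, False, False, False])
    chi2_obs = sv.logrank_z(t, e, obs_group) ** 2
    perms = [
        sv.logrank_z(t, e, np.isin(np.arange(6), idx)) ** 2
        for idx in itertools.combinations(range(6), 3)
    ]
    p_perm = np.mean(np.array(perms) >= chi2_obs - 1e-12)
    _, p_chi2, _ = sv.logrank_test(t, e, obs_group)
    # oracle resolution is 1/20
    assert abs(p_chi2 - p_perm) <= 2 / 20


def test_logrank_type_i_error_calibrated(rng):
    n, reps, alpha = 40, 400, 0.05
    rej = 0
    for _ in range(reps):
        t = rng.exponential(10, n)
        g = rng.permutation(np.arange(n) < n // 2)
        z = sv.logrank_z(t, np.ones(n, int), g)
        if stats.chi2.sf(z * z, 1) < alpha:
            rej += 1
    half = 2.576 * np.sqrt(alpha * (1 - alpha) / reps)
    assert alpha - half <= rej / reps <= alpha + half


def test_logrank_empty_group_errors():
    with pytest.raises(CnError):
        sv.logrank_test([1, 2], [1, 1], ["a", "a"])


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def _efron_loglik(beta, t, e, x):
    """Independent partial-likelihood evaluator (Efron ties), one covariate."""
    ll = 0.0
    risk = np.exp(beta * x)
    for tt in np.unique(t[e == 1]):
        D = (t == tt) & (e == 1)
        R = t >= tt
        d = int(D.sum())
        sum_r, sum_d = risk[R].sum(), risk[D].sum()
        ll += beta * x[D].sum()
        for j in range(d):
            ll -= np.log(sum_r - (j / d) * sum_d)
    return ll


def test_cox_identical_arms_beta_zero():
    t = [2, 4, 6, 8, 10, 12]
    e = [1, 1, 0, 1, 0, 1]
    df = pd.DataFrame(
        {"time_months": t + t, "event": e + e, "arm": ["a"] * 6 + ["b"] * 6}
    )
    fit = sv.cox_fit(df, terms=["arm"])
    assert abs(fit.beta.iloc[0]) < 1e-6


def test_cox_beta_matches_grid_search_oracle(rng):
    n = 60
    x = rng.normal(0, 1, n)
    t = rng.exponential(np.exp(-0.8 * x))
    t = np.round(t, 1) + 0.1  # introduce ties to exercise Efron handling
    e = rng.integers(0, 2, n) | 1  # mostly events
    df = pd.DataFrame({"time_months": t, "event": e, "x": x})
    fit = sv.cox_fit(df, terms=["x"])
    grid = np.arange(-3, 3, 1e-3)
    lls = [_efron_loglik(b, t, e, x) for b in grid]
    b0 = grid[int(np.argmax(lls))]
    fine = np.arange(b0 - 2e-3, b0 + 2e-3, 1e-5)
    b_star = fine[int(np.argmax([_efron_loglik(b, t, e, x) for b in fine]))]
    assert fit.beta.iloc[0] == pytest.approx(b_star, abs=1e-4)
    # local maximality of the reported optimum
    bhat = float(fit.beta.iloc[0])
    assert _efron_loglik(bhat, t, e, x) >= _efron_loglik(bhat + 0.01, t, e, x)
    assert _efron_loglik(bhat, t, e, x) >= _efron_loglik(bhat - 0.01, t, e, x)
    assert fit.log_likelihood == pytest.approx(_efron_loglik(bhat, t, e, x), rel=1e-6)


def test_cox_no_events_errors():
    df = pd.DataFrame({"time_months": [1, 2], "event": [0, 0], "x": [0.0, 1.0]})
    with pytest.raises(CnError):
        sv.cox_fit(df, terms=["x"])


def test_backward_selection_drops_noise_keeps_signal():
    kept_ok = 0
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n = 400
        strong = rng.integers(0, 2, n)
        noise = rng.normal(0, 1, n)
        t = rng.exponential(np.exp(-np.log(3.0) * strong))
        df = pd.DataFrame(
            {"time_months": t, "event": np.ones(n, int),
             "strong": strong.astype(float), "noise": noise}
        )
        retained, fit, dropped = sv.backward_select(df, ["strong", "noise"])
        if retained == ["strong"]:
            kept_ok += 1
    assert kept_ok >= 4


def test_backward_selection_trivial_cases(rng):
    n = 200
    x = rng.integers(0, 2, n)
    t = rng.exponential(np.exp(-1.2 * x))
    df = pd.DataFrame({"time_months": t, "event": np.ones(n, int), "x": x.astype(float)})
    retained, fit, _ = sv.backward_select(df, ["x"])
    assert retained == ["x"] and fit is not None
    # pure-noise single term -> null model
    df["z"] = rng.normal(0, 1, n)
    retained, fit, dropped = sv.backward_select(df, ["z"])
    assert retained == [] and fit is None and len(dropped) == 1
    with pytest.raises(CnError):
        sv.backward_select(df, [])


# ---------------------------------------------------------------------------
# maximally selected cutpoint
# ---------------------------------------------------------------------------

def test_cutpoint_exhaustive_scan_example():
    values = np.arange(1, 11, dtype=float)
    time = np.where(values > 5, values - 5, 50.0)
    event = (values > 5).astype(int)
    res = sv.max_sel_cutpoint(values, time, event, minprop=0.1)
    assert res.cutoff == 5.0
    # oracle: the selected candidate maximizes |z| over the admissible scan
    assert np.abs(res.statistics).max() == pytest.approx(abs(res.statistic))


def test_cutpoint_minprop_excludes_extreme_splits():
    values = np.arange(1, 11, dtype=float)
    time = np.where(values == 10, 1.0, 50.0)
    event = (values == 10).astype(int)
    res = sv.max_sel_cutpoint(values, time, event, minprop=0.2)
    assert res.candidates.max() == 8.0  # split at 9 would leave <20% on one side


def test_cutpoint_constant_values_error():
    with pytest.raises(CnError, match="admissible"):
        sv.max_sel_cutpoint(np.ones(20), np.arange(20) + 1.0, np.ones(20, int))


def test_cutpoint_invariant_under_monotone_transform(rng):
    values = rng.uniform(0, 40, 80)
    time = rng.exponential(20, 80)
    event = rng.integers(0, 2, 80)
    a = sv.max_sel_cutpoint(values, time, event)
    b = sv.max_sel_cutpoint(np.exp(values / 10), time, event)
    assert b.cutoff == pytest.approx(np.exp(a.cutoff / 10))
    assert b.statistic == pytest.approx(a.statistic, abs=1e-9)


# ---------------------------------------------------------------------------
# survival tree
# ---------------------------------------------------------------------------

def test_tree_root_splits_on_strong_binary_factor(rng):
    n = 300
    f = rng.integers(0, 2, n)
    t = rng.exponential(np.exp(-np.log(3.0) * f))
    df = pd.DataFrame(
        {"time_months": t, "event": np.ones(n, int),
         "strong": np.where(f == 1, "hi", "lo"), "junk": rng.choice(["a", "b"], n)}
    )
    tree = sv.survival_tree(df, ["junk", "strong"])
    assert tree.factor == "strong"


def test_tree_insignificant_factor_gives_single_leaf(rng):
    n = 100
    df = pd.DataFrame(
        {"time_months": rng.exponential(10, n), "event": np.ones(n, int),
         "f": rng.choice(["a", "b"], n)}
    )
    # permuted factor carries no survival signal on average; use fixed seed data
    tree = sv.survival_tree(df, ["f"], alpha=1e-6)
    assert tree.is_leaf


# ---------------------------------------------------------------------------
# Fisher r x c
# ---------------------------------------------------------------------------

def _fisher_2x2_closed_form(table):
    """Hypergeometric closed-form two-sided p (probability criterion)."""
    (a, b), (c, d) = table
    n1, n2, m = a + b, c + d, a + c
    k = np.arange(max(0, m - n2), min(m, n1) + 1)
    pmf = stats.hypergeom.pmf(k, n1 + n2, n1, m)
    p_obs = stats.hypergeom.pmf(a, n1 + n2, n1, m)
    return pmf[pmf <= p_obs * (1 + 1e-9)].sum()


@pytest.mark.parametrize(
    "table",
    [
        [[3, 7], [9, 2]],
        [[10, 10], [10, 10]],
        [[1, 20], [15, 2]],
        [[0, 5], [8, 3]],
    ],
)
def test_fisher_2x2_matches_hypergeometric(table):
    assert sv.fisher_rxc(table, mode="exact") == pytest.approx(
        _fisher_2x2_closed_form(table), abs=1e-12
    )


def test_fisher_exact_rxc_matches_reference_value():
    # independent oracle: R fisher.test (FEXACT) on this 3x3 gives 0.0802332290716
    table = [[5, 2, 3], [1, 7, 2], [4, 2, 6]]
    assert sv.fisher_rxc(table, mode="exact") == pytest.approx(0.0802332290716, abs=1e-10)


def test_fisher_montecarlo_converges_to_exact():
    table = [[12, 5], [4, 14]]
    exact = sv.fisher_rxc(table, mode="exact")
    mc = sv.fisher_rxc(table, mode="montecarlo", n_mc=40_000, seed=5)
    se = np.sqrt(exact * (1 - exact) / 40_000)
    assert abs(mc - exact) <= 3 * se


def test_fisher_degenerate_single_column_is_one():
    assert sv.fisher_rxc([[3, 0], [5, 0]]) == 1.0


def test_fisher_budget_exceeded_instructs_montecarlo():
    big = (np.ones((4, 4), dtype=int) * 40).tolist()
    with pytest.raises(CnError, match="montecarlo"):
        sv.fisher_rxc(big, mode="exact", budget=1000)


# ---------------------------------------------------------------------------
# one-way ANOVA
# ---------------------------------------------------------------------------

def test_anova_identical_groups_null():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    F, p = sv.oneway_anova(np.r_[v, v], ["a"] * 4 + ["b"] * 4)
    assert F == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)


def test_anova_two_groups_equals_squared_t(rng):
    a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1, 25)
    F, p = sv.oneway_anova(np.r_[a, b], ["a"] * 30 + ["b"] * 25)
    tt = stats.ttest_ind(a, b, equal_var=True)
    assert F == pytest.approx(tt.statistic**2, abs=1e-9)
    assert p == pytest.approx(tt.pvalue, abs=1e-9)


def test_anova_type_i_error_calibrated(rng):
    reps, alpha, rej = 500, 0.05, 0
    for _ in range(reps):
        v = rng.normal(0, 1, 45)
        g = np.repeat(["a", "b", "c"], 15)
        if sv.oneway_anova(v, g)[1] < alpha:
            rej += 1
    half = 2.576 * np.sqrt(alpha * (1 - alpha) / reps)
    assert alpha - half <= rej / reps <= alpha + half


def test_anova_empty_group_errors():
    with pytest.raises(CnError):
        sv.oneway_anova([1.0, 2.0], ["a", "a"])


# ---------------------------------------------------------------------------
# level shares (evaluable-percentage bookkeeping)
# ---------------------------------------------------------------------------

def test_level_share_excludes_missing():
    s = pd.Series(["aberrant"] * 3 + ["normal"] * 5 + ["missing"] * 2)
    count, total, pct = sv.level_share(s, "aberrant")
    assert (count, total, pct) == (3, 8, 37.5)
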