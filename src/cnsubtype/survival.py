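"""Survival estimation and the association-test battery.

Implements the statistical toolkit the subgroup analysis rests on:

* Kaplan-Meier product-limit curves with Greenwood variance and log-scale
  confidence intervals, right-truncated for reporting when fewer than 10%
  of a group remains at risk;
* the (unweighted) log-rank test, including a fast two-group standardized
  statistic used by the cutpoint scan and the survival tree;
* Cox proportional-hazards fits (Efron tie handling, via lifelines) with
  stepwise backward factor selection at p < 0.10 (likelihood-ratio p per
  factor);
* a maximally selected survival cutpoint for dichotomizing a continuous
  marker (genome instability index);
* a simplified greedy log-rank survival tree over categorical factors;
* Fisher's exact test for r x c contingency tables (full enumeration, or
  Monte Carlo over the Patefield null when enumeration is infeasible) and
  one-way ANOVA for continuous covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .cn_core import CnError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate for one group.

    ``times`` are the distinct observed times (events or censorings) in
    increasing order; ``surv`` the estimate just after each time. CIs are on
    the log-survival (plain Greenwood) scale. ``trunc_time`` is the first
    time at which fewer than 10% of the group remains at risk — a reporting
    limit, not a data modification.
    """

    n: int
    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    trunc_time: float | None


def km_fit(time, event) -> KMCurve:
    """Kaplan-Meier estimator with Greenwood log-scale 95% CI."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time < 0):
        raise CnError("negative survival times")
    if time.size == 0:
        raise CnError("empty group")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq, start = np.unique(time, return_index=True)
    n = time.size
    at_risk = n - start
    d = np.add.reduceat(event, start)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 1.0 - d / at_risk
        surv = np.cumprod(frac)
        # Greenwood variance of log S
        varlog = np.cumsum(np.where(at_risk > d, d / (at_risk * (at_risk - d)), np.inf))
        se = np.sqrt(varlog)
        lo = surv * np.exp(-Z95 * se)
        hi = np.minimum(1.0, surv * np.exp(Z95 * se))
    lo = np.where(surv > 0, lo, 0.0)
    hi = np.where(surv > 0, hi, 0.0)
    below = at_risk - d < 0.10 * n
    trunc = float(uniq[below][0]) if below.any() else None
    return KMCurve(n, uniq, surv, at_risk, d, lo, hi, trunc)


def km_by_group(time, event, group) -> dict[str, KMCurve]:
    group = pd.Series(np.asarray(group, dtype=object))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out = {}
    for g in pd.unique(group):
        sel = (group == g).to_numpy()
        out[str(g)] = km_fit(time[sel], event[sel])
    return out


def survival_at(curve: KMCurve, t: float) -> tuple[float, float, float, bool]:
    """Step-function evaluation S(t) with its CI.

    Returns (estimate, ci_low, ci_high, beyond_followup_flag).
    """
    if t < 0:
        raise CnError("t must be >= 0")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    beyond = t > curve.times[-1]
    if idx < 0:
        return 1.0, 1.0, 1.0, beyond
    return (
        float(curve.surv[idx]),
        float(curve.ci_low[idx]),
        float(curve.ci_high[idx]),
        bool(beyond),
    )


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def logrank_z(time, event, in_group1) -> float:
    """Standardized two-group log-rank statistic (O1 - E1) / sqrt(V).

    Positive when group 1 has MORE events than expected under the null.
    Returns 0.0 when the variance is zero (no informative event times).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    order = np.argsort(time, kind="stable")
    time, event, g1 = time[order], event[order], g1[order]
    uniq, start = np.unique(time, return_index=True)
    n_tot = time.size
    at_risk = n_tot - start
    # at risk in group 1 at each distinct time = total g1 minus those removed before
    cum_g1 = np.concatenate([[0], np.cumsum(g1)])
    n1 = int(g1.sum()) - cum_g1[start]
    d = np.add.reduceat(event, start)
    d1 = np.add.reduceat(event * g1, start)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = d * n1 / at_risk
        v = np.where(
            at_risk > 1,
            d * (n1 / at_risk) * (1.0 - n1 / at_risk) * (at_risk - d) / (at_risk - 1.0),
            0.0,
        )
    V = float(np.nansum(v))
    if V <= 0:
        return 0.0
    return float((d1.sum() - np.nansum(e1)) / np.sqrt(V))


def logrank_test(time, event, group) -> tuple[float, float, int]:
    """Unweighted k-group log-rank test; returns (chi2, p, df)."""
    from lifelines.statistics import multivariate_logrank_test

    group = np.asarray(group, dtype=object)
    levels, counts = np.unique(group, return_counts=True)
    if len(levels) < 2:
        raise CnError("log-rank needs at least two groups")
    if (counts == 0).any():
        raise CnError("empty group in log-rank test")
    res = multivariate_logrank_test(np.asarray(time, float), group, np.asarray(event, int))
    return float(res.test_statistic), float(res.p_value), len(levels) - 1


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted proportional-hazards model.

    ``terms`` maps each model term (factor or numeric covariate) to its
    design columns; per-column estimates are on the log-hazard scale with
    Wald 95% CIs. ``log_likelihood`` is the log partial likelihood at the
    optimum.
    """

    duration_col: str
    event_col: str
    terms: dict[str, list[str]]
    beta: pd.Series
    hr: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    p: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.beta,
                "HR": self.hr,
                "HR_low95": self.ci_low,
                "HR_high95": self.ci_high,
                "p": self.p,
            }
        )


def _encode_terms(
    df: pd.DataFrame, terms: Sequence[str], ref_levels: Mapping[str, str] | None = None
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand categorical terms to treatment-coded dummies (drop reference)."""
    ref_levels = dict(ref_levels or {})
    X = pd.DataFrame(index=df.index)
    term_map: dict[str, list[str]] = {}
    for t in terms:
        col = df[t]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            X[t] = col.astype(float)
            term_map[t] = [t]
        else:
            col = col.astype(str)
            levels = sorted(col.dropna().unique())
            ref = ref_levels.get(t, levels[0])
            if ref not in levels:
                raise CnError(f"reference level {ref!r} not observed for term {t!r}")
            cols = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{t}[{lev}]"
                X[name] = (col == lev).astype(float)
                cols.append(name)
            term_map[t] = cols
    return X, term_map


def cox_fit(
    df: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    terms: Sequence[str] | None = None,
    ref_levels: Mapping[str, str] | None = None,
) -> CoxFit:
    """Fit a Cox model by partial-likelihood maximization (Efron ties).

    Categorical terms are treatment-coded against an explicit (or first
    alphabetical) reference level, whose hazard ratio is identically 1.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if terms is None:
        terms = [c for c in df.columns if c not in (duration_col, event_col)]
    if int(df[event_col].sum()) < 1:
        raise CnError("Cox model needs at least one event")
    X, term_map = _encode_terms(df, terms, ref_levels)
    data = pd.concat([df[[duration_col, event_col]], X], axis=1).dropna()
    warns: list[str] = []
    cph = CoxPHFitter()
    import warnings as _w

    with _w.catch_warnings(record=True) as caught:
        _w.simplefilter("always")
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as e:  # pragma: no cover - surfaced to caller
            raise CnError(f"Cox model did not converge: {e}") from e
    for w in caught:
        msg = str(w.message)
        if "complete separation" in msg or "convergence" in msg.lower():
            warns.append(msg.splitlines()[0])
    s = cph.summary
    return CoxFit(
        duration_col=duration_col,
        event_col=event_col,
        terms=term_map,
        beta=s["coef"],
        hr=s["exp(coef)"],
        ci_low=s["exp(coef) lower 95%"],
        ci_high=s["exp(coef) upper 95%"],
        p=s["p"],
        log_likelihood=float(cph.log_likelihood_),
        n=len(data),
        n_events=int(data[event_col].sum()),
        warnings=warns,
    )


def term_lr_pvalues(
    df: pd.DataFrame,
    fit: CoxFit,
    terms: Sequence[str],
    ref_levels: Mapping[str, str] | None = None,
) -> pd.Series:
    """Likelihood-ratio p per model term (drop the whole factor, refit)."""
    out = {}
    for t in terms:
        reduced_terms = [x for x in terms if x != t]
        if reduced_terms:
            reduced = cox_fit(df, fit.duration_col, fit.event_col, reduced_terms, ref_levels)
            ll0 = reduced.log_likelihood
        else:
            ll0 = _null_loglik(df, fit.duration_col, fit.event_col)
        lr = 2.0 * (fit.log_likelihood - ll0)
        dof = len(fit.terms[t])
        out[t] = float(stats.chi2.sf(max(lr, 0.0), dof))
    return pd.Series(out)


def _null_loglik(df: pd.DataFrame, duration_col: str, event_col: str) -> float:
    """Log partial likelihood of the empty (no-covariate) model, Efron ties."""
    time = df[duration_col].to_numpy(float)
    event = df[event_col].to_numpy(int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    uniq, start = np.unique(time, return_index=True)
    n_at = time.size - start
    d = np.add.reduceat(event, start)
    ll = 0.0
    for ni, di in zip(n_at, d):
        for j in range(int(di)):
            ll -= np.log(ni - j * 1.0)  # Efron: risk set shrinks by d_i/d_i steps
    return float(ll)


def backward_select(
    df: pd.DataFrame,
    terms: Sequence[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    threshold: float = 0.10,
    ref_levels: Mapping[str, str] | None = None,
) -> tuple[list[str], CoxFit | None, list[tuple[str, float]]]:
    """Stepwise backward factor selection on a Cox model.

    Repeatedly drops the term with the largest likelihood-ratio p >= the
    threshold and refits, until all retained terms are below the threshold.
    Whole factors (all dummy levels) are dropped together. Returns
    (retained terms, final fit or None if the null model remains, drop log).
    """
    terms = list(terms)
    if not terms:
        raise CnError("backward selection needs a non-empty starting term list")
    dropped: list[tuple[str, float]] = []
    while terms:
        fit = cox_fit(df, duration_col, event_col, terms, ref_levels)
        pvals = term_lr_pvalues(df, fit, terms, ref_levels)
        worst = pvals.idxmax()
        if pvals[worst] < threshold:
            return terms, fit, dropped
        dropped.append((str(worst), float(pvals[worst])))
        terms = [t for t in terms if t != worst]
    return [], None, dropped


# ---------------------------------------------------------------------------
# Maximally selected survival cutpoint
# ---------------------------------------------------------------------------

@dataclass
class CutpointResult:
    """Outcome of a maximally selected log-rank cutpoint scan."""

    cutoff: float
    statistic: float  # standardized log-rank z at the cutoff
    candidates: np.ndarray
    statistics: np.ndarray
    minprop: float

    def classify(self, values) -> np.ndarray:
        """Dichotomize values at the selected cutoff: 'low' (<=) / 'high'."""
        v = np.asarray(values, dtype=float)
        return np.where(v <= self.cutoff, "low", "high")


def max_sel_cutpoint(values, time, event, minprop: float = 0.1) -> CutpointResult:
    """Survival-based dichotomization threshold for a continuous marker.

    Candidates are the unique observed values whose low/high split leaves at
    least ``minprop`` of the samples on each side; for each candidate the
    standardized two-group log-rank statistic is computed, and the cutoff
    maximizing |z| is selected (ties broken toward the smaller cutoff).
    Rank-based by construction: any strictly monotone transform of the
    values moves the cutoff to the transformed scale but not the split.
    """
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not np.isfinite(values).all():
        raise CnError("marker values must be finite")
    n = values.size
    if n < 10:
        raise CnError("cutpoint selection needs at least 10 samples")
    uniq = np.unique(values)
    n_low = np.searchsorted(np.sort(values), uniq, side="right")
    ok = (n_low >= minprop * n) & ((n - n_low) >= minprop * n)
    candidates = uniq[ok]
    if candidates.size == 0:
        raise CnError("no admissible cutpoint (constant marker or minprop too strict)")
    zs = np.array([logrank_z(time, event, values > c) for c in candidates])
    best = int(np.argmax(np.abs(zs)))  # argmax returns the FIRST max -> smaller cutoff
    return CutpointResult(float(candidates[best]), float(zs[best]), candidates, zs, minprop)


# ---------------------------------------------------------------------------
# Simplified survival tree
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of the greedy log-rank survival tree."""

    n: int
    n_events: int
    depth: int
    factor: str | None = None
    left_levels: tuple[str, ...] = ()
    right_levels: tuple[str, ...] = ()
    chi2: float | None = None
    p: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.factor is None

    def describe(self, indent: str = "") -> str:
        if self.is_leaf:
            return f"{indent}leaf n={self.n} events={self.n_events}"
        head = (
            f"{indent}split {self.factor}: {list(self.left_levels)} | "
            f"{list(self.right_levels)} (chi2={self.chi2:.2f}, p={self.p:.3g})"
        )
        return "\n".join(
            [head, self.left.describe(indent + "  "), self.right.describe(indent + "  ")]
        )


def _level_partitions(levels: list[str]):
    """All binary partitions of a level set (first level fixed to the left)."""
    rest = levels[1:]
    for mask in range(2 ** len(rest)):
        left = [levels[0]] + [l for i, l in enumerate(rest) if mask >> i & 1]
        right = [l for i, l in enumerate(rest) if not mask >> i & 1]
        if right:
            yield tuple(left), tuple(right)


def survival_tree(
    df: pd.DataFrame,
    factors: Sequence[str],
    duration_col: str = "time_months",
    event_col: str = "event",
    max_depth: int = 2,
    min_node: int = 20,
    alpha: float = 0.05,
    _depth: int = 0,
) -> TreeNode:
    """Greedy recursive partitioning of survival by categorical factors.

    At each node, every binary partition of every factor's observed levels
    is scored by the two-group log-rank chi-square; the best split is kept
    if its nominal chi-square(1) p-value is below ``alpha``. Recursion stops
    at ``max_depth`` or when a node holds fewer than ``min_node`` samples.
    This is a simplified CART-style partitioner, not rpart's
    exponential-scaling method.
    """
    if not factors:
        raise CnError("survival tree needs at least one factor")
    time = df[duration_col].to_numpy(float)
    event = df[event_col].to_numpy(int)
    node = TreeNode(n=len(df), n_events=int(event.sum()), depth=_depth)
    if _depth >= max_depth or len(df) < min_node or event.sum() == 0:
        return node
    best = None
    for f in factors:
        col = df[f].astype(str)
        levels = sorted(col.unique())
        if len(levels) < 2:
            continue
        for left, right in _level_partitions(levels):
            z = logrank_z(time, event, col.isin(left).to_numpy())
            chi2 = z * z
            if best is None or chi2 > best[0]:
                best = (chi2, f, left, right)
    if best is None:
        return node
    chi2, f, left, right = best
    p = float(stats.chi2.sf(chi2, 1))
    if p >= alpha:
        return node
    node.factor, node.left_levels, node.right_levels = f, left, right
    node.chi2, node.p = float(chi2), p
    sel = df[f].astype(str).isin(left)
    kw = dict(
        duration_col=duration_col,
        event_col=event_col,
        max_depth=max_depth,
        min_node=min_node,
        alpha=alpha,
        _depth=_depth + 1,
    )
    node.left = survival_tree(df[sel], factors, **kw)
    node.right = survival_tree(df[~sel], factors, **kw)
    return node


# ---------------------------------------------------------------------------
# Fisher's exact test for r x c tables
# ---------------------------------------------------------------------------

def _table_logprob(tables, row, col, n_total):
    const = gammaln(row + 1).sum() + gammaln(col + 1).sum() - gammaln(n_total + 1)
    return const - gammaln(np.asarray(tables, dtype=float) + 1).sum(axis=(-2, -1))


def _enumerate_2xc(table, budget):
    """Vectorized enumeration of all 2 x c tables with the observed margins."""
    row, col = table.sum(1), table.sum(0)
    est = int(np.prod(col[:-1] + 1))
    if est > budget:
        raise CnError(
            f"exact enumeration would visit ~{est} tables (> budget {budget}); use montecarlo"
        )
    grids = np.meshgrid(*[np.arange(c + 1) for c in col[:-1]], indexing="ij")
    A = np.stack([g.ravel() for g in grids], axis=1)
    last = row[0] - A.sum(1)
    keep = (last >= 0) & (last <= col[-1])
    A = np.concatenate([A[keep], last[keep, None]], axis=1)
    return np.stack([A, col[None, :] - A], axis=1)


def _enumerate_rxc(table, budget):
    """Depth-first enumeration of r x c tables with fixed margins.

    Fills the table row by row; within a row, cell by cell, bounded by the
    remaining column capacity. Intended for small tables — raises once more
    than ``budget`` tables have been emitted.
    """
    row = table.sum(1).astype(int)
    col = table.sum(0).astype(int)
    r, c = len(row), len(col)
    out: list[np.ndarray] = []

    def fill_row(i, remaining_col, rows):
        if i == r - 1:
            if len(out) >= budget:
                raise CnError(f"exact enumeration exceeded budget {budget}; use montecarlo")
            out.append(np.vstack(rows + [remaining_col]))
            return
        target = int(row[i])

        def fill_cell(j, left, cur):
            if j == c - 1:
                if 0 <= left <= remaining_col[j]:
                    cand = np.array(cur + [left])
                    fill_row(i + 1, remaining_col - cand, rows + [cand])
                return
            # cell value bounded by the row remainder and the column capacity;
            # also leave enough for the rest of the row to be feasible
            hi = min(int(remaining_col[j]), left)
            lo = max(0, left - int(remaining_col[j + 1 :].sum()))
            for v in range(lo, hi + 1):
                fill_cell(j + 1, left - v, cur + [v])

        fill_cell(0, target, [])

    fill_row(0, col.copy(), [])
    return np.array(out)


def fisher_rxc(
    table,
    mode: str = "exact",
    n_mc: int = 1_000_000,
    seed=None,
    budget: int = 5_000_000,
) -> float:
    """Two-sided Fisher exact p for an r x c contingency table.

    Two-sidedness follows the probability criterion: p is the total null
    (multivariate hypergeometric) probability of tables, with the observed
    margins, whose probability is at most that of the observed table
    (ties included up to floating-point tolerance).

    ``mode="exact"`` enumerates all tables with the observed margins
    (vectorized for 2 x c; depth-first otherwise) and errors above
    ``budget`` tables. ``mode="montecarlo"`` samples ``n_mc`` tables from
    the margin-conditioned null (Patefield's algorithm) and reports
    p = (1 + #{prob(sampled) <= prob(observed)}) / (n_mc + 1).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or np.any(table < 0):
        raise CnError("table must be a 2-D array of nonnegative counts")
    # empty rows/columns carry no information under fixed margins
    table = table[table.sum(1) > 0][:, table.sum(0) > 0]
    if table.size == 0:
        raise CnError("empty table")
    if min(table.shape) < 2:
        return 1.0  # a single row/column is the only table with these margins
    row, col = table.sum(1), table.sum(0)
    n_total = int(table.sum())
    lp_obs = float(_table_logprob(table, row, col, n_total))
    tol = 64 * np.finfo(float).eps * abs(lp_obs)

    if mode == "exact":
        if table.shape[0] == 2:
            tabs = _enumerate_2xc(table, budget)
        elif table.shape[1] == 2:
            tabs = _enumerate_2xc(table.T, budget).transpose(0, 2, 1)
        else:
            tabs = _enumerate_rxc(table, budget)
        lp = _table_logprob(tabs, row, col, n_total)
        return float(min(1.0, np.exp(lp[lp <= lp_obs + tol]).sum()))

    if mode == "montecarlo":
        if n_mc < 100:
            raise CnError("montecarlo mode needs n_mc >= 100")
        rng = np.random.default_rng(seed)
        rt = stats.random_table(row, col)
        chunk = 200_000
        count = 0
        left = int(n_mc)
        while left > 0:
            m = min(chunk, left)
            samp = rt.rvs(m, random_state=rng)
            if m == 1:
                samp = samp[None, ...]
            count += int((_table_logprob(samp, row, col, n_total) <= lp_obs + tol).sum())
            left -= m
        return (1 + count) / (n_mc + 1)

    raise CnError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# One-way ANOVA and the Table-1 style battery
# ---------------------------------------------------------------------------

def oneway_anova(values, group) -> tuple[float, float]:
    """Classical between/within one-way F test; returns (F, p)."""
    values = np.asarray(values, dtype=float)
    group = np.asarray(group, dtype=object)
    arrays = [values[group == g] for g in pd.unique(group)]
    if len(arrays) < 2:
        raise CnError("ANOVA needs at least two groups")
    if any(a.size == 0 for a in arrays):
        raise CnError("empty group in ANOVA")
    res = stats.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


def level_share(series: pd.Series, level: str, missing=("missing", "")) -> tuple[int, int, float]:
    """Count and percent of evaluable (non-missing) entries at a level.

    Returns (count, n_evaluable, percent rounded to 0.1).
    """
    s = series.dropna().astype(str)
    s = s[~s.isin(missing)]
    count = int((s == level).sum())
    total = int(len(s))
    if total == 0:
        raise CnError("no evaluable entries")
    return count, total, round(100.0 * count / total, 1)


def association_tests(
    df: pd.DataFrame,
    by: str,
    categorical: Sequence[str] = (),
    continuous: Sequence[str] = (),
    n_mc: int = 100_000,
    seed=None,
    exact_budget: int = 2_000_000,
) -> pd.DataFrame:
    """Table-1 style association battery against a grouping column.

    Categorical variables (missing entries excluded) are tested by Fisher's
    exact test — full enumeration when feasible, Monte Carlo otherwise;
    continuous variables by one-way ANOVA. Returns variable, test used, p.
    """
    rows = []
    groups = df[by].astype(str)
    for var in categorical:
        col = df[var]
        ok = col.notna() & ~col.astype(str).isin(("missing", ""))
        tab = pd.crosstab(col[ok].astype(str), groups[ok]).to_numpy()
        try:
            p = fisher_rxc(tab, mode="exact", budget=exact_budget)
            method = "fisher_exact"
        except CnError:
            p = fisher_rxc(tab, mode="montecarlo", n_mc=n_mc, seed=seed)
            method = "fisher_montecarlo"
        rows.append((var, method, p))
    for var in continuous:
        ok = df[var].notna()
        _, p = oneway_anova(df.loc[ok, var].astype(float), groups[ok])
        rows.append((var, "oneway_anova", p))
    return pd.DataFrame(rows, columns=["variable", "test", "p"]).set_index("variable")


# ---------------------------------------------------------------------------
# Optional KM plot export
# ---------------------------------------------------------------------------

def plot_km(curves: Mapping[str, KMCurve], path, title: str = "") -> None:
    """Export a simple stepped KM plot (curves right-truncated at 10% at risk)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for name, c in curves.items():
        t = np.concatenate([[0.0], c.times])
        s = np.concatenate([[1.0], c.surv])
        if c.trunc_time is not None:
            keep = t <= c.trunc_time
            t, s = t[keep], s[keep]
        ax.step(t, s, where="post", label=f"{name} (n={c.n})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
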