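"""Assembly of the full subgroup analysis into a machine-readable report."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import STRATA, composition_table
from . import survival as sv


def _km_block(curve: sv.KMCurve, at_months: float = 60.0) -> dict:
    s, lo, hi, beyond = sv.survival_at(curve, at_months)
    return {
        "n": curve.n,
        "events": int(curve.n_events.sum()),
        "crs_at_months": at_months,
        "crs": round(100.0 * s, 1),
        "crs_ci95": [round(100.0 * lo, 1), round(100.0 * hi, 1)],
        "beyond_followup": beyond,
        "truncation_months": curve.trunc_time,
    }


def analyze_cohort(
    clinical: pd.DataFrame,
    stratum_col: str = "stratum",
    duration_col: str = "time_months",
    event_col: str = "event",
    covariates: Sequence[str] = (),
    cox_terms: Sequence[str] | None = None,
    gii_col: str | None = None,
    minprop: float = 0.1,
    crs_at: float = 60.0,
    seed=None,
) -> dict:
    """Run the subgroup survival/association battery and return a report dict.

    Expects a per-sample table with the four-stratum label, follow-up time
    in months and the cancer-related-death indicator; optionally a GII
    column (cutpoint selection + dichotomization) and clinicopathological
    covariates (association tests against the strata).
    """
    df = clinical.dropna(subset=[stratum_col, duration_col, event_col]).copy()
    report: dict = {"n": len(df), "n_events": int(df[event_col].sum())}

    comp = composition_table(df[stratum_col])
    report["composition"] = {
        s: {"n": int(comp.loc[s, "n"]), "percent": float(comp.loc[s, "percent"])}
        for s in comp.index
    }

    no_events = report["n_events"] == 0
    time = df[duration_col].to_numpy(float)
    event = df[event_col].to_numpy(int)

    curves = sv.km_by_group(time, event, df[stratum_col])
    report["survival_by_stratum"] = {g: _km_block(c, crs_at) for g, c in curves.items()}

    if no_events or df[stratum_col].nunique() < 2:
        report["logrank"] = None
        report["cox_stratum"] = None
    else:
        chi2, p, dof = sv.logrank_test(time, event, df[stratum_col])
        report["logrank"] = {"chi2": chi2, "p": p, "df": dof}
        ref = STRATA[0] if STRATA[0] in set(df[stratum_col]) else sorted(df[stratum_col])[0]
        fit = sv.cox_fit(df, duration_col, event_col, [stratum_col], {stratum_col: ref})
        report["cox_stratum"] = {
            "reference": ref,
            "terms": {
                name: {
                    "HR": round(float(fit.hr[name]), 3),
                    "ci95": [round(float(fit.ci_low[name]), 3), round(float(fit.ci_high[name]), 3)],
                    "p": float(fit.p[name]),
                }
                for name in fit.hr.index
            },
        }

    if gii_col is not None and not no_events:
        cut = sv.max_sel_cutpoint(df[gii_col].to_numpy(float), time, event, minprop)
        gii_class = cut.classify(df[gii_col])
        df["gii_class"] = gii_class
        n_low = int((gii_class == "low").sum())
        lr = sv.logrank_test(time, event, gii_class) if len(set(gii_class)) == 2 else None
        report["gii_cutpoint"] = {
            "cutoff": round(cut.cutoff, 2),
            "statistic": round(cut.statistic, 3),
            "n_low": n_low,
            "n_high": len(df) - n_low,
            "logrank_p": lr[1] if lr else None,
        }
    else:
        report["gii_cutpoint"] = None

    if cox_terms and not no_events:
        retained, fit, dropped = sv.backward_select(
            df, list(cox_terms), duration_col, event_col
        )
        report["backward_selection"] = {
            "retained": retained,
            "dropped": [{"term": t, "p": round(p, 4)} for t, p in dropped],
            "final_model": None
            if fit is None
            else {
                name: {"HR": round(float(fit.hr[name]), 3), "p": float(fit.p[name])}
                for name in fit.hr.index
            },
        }
        factors = [t for t in cox_terms if not pd.api.types.is_numeric_dtype(df[t])]
        if factors:
            tree = sv.survival_tree(df, factors, duration_col, event_col)
            report["survival_tree"] = tree.describe()
        else:
            report["survival_tree"] = None
    else:
        report["backward_selection"] = None
        report["survival_tree"] = None

    if covariates:
        cats = [c for c in covariates if not pd.api.types.is_numeric_dtype(df[c])]
        conts = [c for c in covariates if pd.api.types.is_numeric_dtype(df[c])]
        tests = sv.association_tests(df, stratum_col, cats, conts, seed=seed)
        report["associations"] = {
            str(v): {"test": tests.loc[v, "test"], "p": float(tests.loc[v, "p"])}
            for v in tests.index
        }
    else:
        report["associations"] = None

    return report
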