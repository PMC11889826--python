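"""Response dichotomization, group comparisons, correlations, and survival.

Survival machinery (Kaplan-Meier, log-rank, Cox proportional hazards) is
delegated to lifelines; rank tests and Spearman correlation to scipy. This
module owns the clinical conventions: DCR/SCR at 12 months PFS, censoring
at last contact, and the banded correlation report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CfmonError, ConfigurationError

DCR_CUT_MONTHS = 12.0
RHO_MODERATE = 0.25
RHO_STRONG = 0.70


@dataclass
class SurvivalFit:
    endpoint: str                    # "PFS" | "OS"
    grouping: str
    hazard_ratio: float
    ci95: tuple
    p_value: float
    n_per_group: dict
    covariates: pd.DataFrame | None = None
    logrank_p: float | None = None


def dichotomize_response(pfs_months: float, pfs_event: bool,
                         cut: float = DCR_CUT_MONTHS) -> str:
    """Durable (PFS > cut) vs short (PFS <= cut, with event) clinical
    response; censored before the cut is not evaluable."""
    if pfs_months > cut:
        return "DCR"
    if pfs_event:
        return "SCR"
    return "not_evaluable"


def km_logrank(times, events, group_labels) -> dict:
    """Two-or-more-group log-rank test plus KM curve coordinates."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(group_labels)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ConfigurationError("log-rank needs >= 2 groups")
    if not events.any():
        raise ConfigurationError("log-rank needs >= 1 event")
    res = multivariate_logrank_test(times, groups, events)
    curves = {}
    for g in uniq:
        sel = groups == g
        km = KaplanMeierFitter()
        km.fit(times[sel], events[sel], label=str(g))
        sf = km.survival_function_
        curves[str(g)] = pd.DataFrame({
            "time": sf.index.to_numpy(),
            "survival": sf.iloc[:, 0].to_numpy(),
        })
        curves[str(g)].attrs["median"] = float(km.median_survival_time_)
    return {"statistic": float(res.test_statistic),
            "p": float(res.p_value),
            "curves": curves,
            "n_per_group": {str(g): int((groups == g).sum()) for g in uniq}}


def cox_fit(times, events, covariate_table: pd.DataFrame,
            formula_cols=None, endpoint: str = "PFS",
            grouping: str = "") -> SurvivalFit:
    """Cox proportional-hazards fit; HR, Wald 95% CI and p per covariate.

    The first column of ``covariate_table`` (or of ``formula_cols``) is
    reported as the headline hazard ratio.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    cols = list(formula_cols) if formula_cols is not None \
        else list(covariate_table.columns)
    df = covariate_table[cols].copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=bool).astype(int)
    n_events = int(df["_event"].sum())
    if n_events < len(cols) + 1:
        raise CfmonError(
            f"Cox fit needs more events ({n_events}) than covariates "
            f"({len(cols)})")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except (ConvergenceError, ValueError) as exc:
        counts = {c: df[c].value_counts().to_dict()
                  for c in cols if df[c].nunique() < 6}
        raise CfmonError(
            f"Cox model did not converge (separation?): {exc}; "
            f"group counts: {counts}")
    summary = cph.summary

    def _exp(x):  # wide Wald bounds may overflow to inf; that is the answer
        with np.errstate(over="ignore"):
            return np.exp(x)

    head = cols[0]
    hr = float(_exp(summary.loc[head, "coef"]))
    ci = (float(_exp(summary.loc[head, "coef lower 95%"])),
          float(_exp(summary.loc[head, "coef upper 95%"])))
    p = float(summary.loc[head, "p"])
    npg = {}
    if df[head].nunique() <= 2:
        npg = {str(k): int(v) for k, v in df[head].value_counts().items()}
    table = pd.DataFrame({
        "covariate": summary.index,
        "hr": _exp(summary["coef"].to_numpy()),
        "ci_low": _exp(summary["coef lower 95%"].to_numpy()),
        "ci_high": _exp(summary["coef upper 95%"].to_numpy()),
        "p": summary["p"].to_numpy(),
    }).reset_index(drop=True)
    return SurvivalFit(endpoint, grouping or head, hr, ci, p, npg, table)


def group_compare(values_a, values_b, paired: bool = False) -> dict:
    """Two-sided Mann-Whitney U (independent) or Wilcoxon (paired) p-value.

    Degenerate all-equal input returns p = 1 with a flag instead of erroring.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if paired and len(a) != len(b):
        raise ConfigurationError("paired comparison needs equal-length inputs")
    if len(a) < 3 or len(b) < 3:
        raise ConfigurationError("need >= 3 values per group")
    if paired:
        diffs = a - b
        if np.all(diffs == 0):
            return {"p": 1.0, "statistic": 0.0, "degenerate": True}
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return {"p": float(res.pvalue), "statistic": float(res.statistic),
                "degenerate": False}
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return {"p": 1.0, "statistic": len(a) * len(b) / 2.0,
                "degenerate": True}
    method = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {"p": float(res.pvalue), "statistic": float(res.statistic),
            "degenerate": False}


def correlation_matrix(score_table: pd.DataFrame,
                       lab_table: pd.DataFrame | None = None,
                       min_pairs: int = 5,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Spearman correlations with moderate/strong banding.

    Rows iterate over ``score_table`` columns, columns over ``lab_table``
    (defaults to ``score_table`` itself). Cells with fewer than ``min_pairs``
    complete pairs are marked not-evaluable.
    """
    other = lab_table if lab_table is not None else score_table
    rows = []
    for x in score_table.columns:
        for y in other.columns:
            xv = score_table[x].to_numpy(dtype=float)
            yv = other[y].to_numpy(dtype=float)
            ok = ~(np.isnan(xv) | np.isnan(yv))
            if ok.sum() < min_pairs:
                rows.append({"x": x, "y": y, "rho": np.nan, "p": np.nan,
                             "n": int(ok.sum()), "band": "not_evaluable"})
                continue
            rho, p = stats.spearmanr(xv[ok], yv[ok])
            if np.isnan(rho):
                band = "not_evaluable"
            elif abs(rho) >= RHO_STRONG and p < alpha:
                band = "strong"
            elif abs(rho) >= RHO_MODERATE and p < alpha:
                band = "moderate"
            else:
                band = "none"
            rows.append({"x": x, "y": y, "rho": float(rho),
                         "p": float(p), "n": int(ok.sum()), "band": band})
    return pd.DataFrame(rows)
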