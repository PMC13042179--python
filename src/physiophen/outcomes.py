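"""Outcome stratification by phenotype.

Group-difference testing (Kruskal-Wallis for continuous variables,
chi-squared for categorical), one-way ANOVA reconstructed from printed
summary statistics (n, mean, sd per group), Kaplan-Meier survival with
log-rank comparison, and day-2/7/28 support-prevalence tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = ["compare_groups", "anova_from_summary", "km_estimate", "logrank",
           "prevalence_at", "GroupComparisonReport", "SurvivalCurves"]

ALPHA = 0.05


@dataclass
class GroupComparisonReport:
    results: pd.DataFrame        # variable, test, statistic, p, significant
    group_summaries: dict = field(default_factory=dict)


def compare_groups(table: pd.DataFrame, variables: dict[str, str],
                   group_col: str = "phenotype") -> GroupComparisonReport:
    """Compare variables across phenotype groups.

    ``variables`` maps column name -> kind ("continuous" uses the
    tie-corrected Kruskal-Wallis test, "categorical" the chi-squared
    test on the contingency table).  Two-tailed significance at 0.05.
    """
    groups = [g for _, g in table.groupby(group_col, observed=True)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    summaries = {}
    for var, kind in variables.items():
        if kind == "continuous":
            samples = [g[var].dropna().to_numpy() for g in groups]
            samples = [s for s in samples if len(s)]
            stat, p = stats.kruskal(*samples)
            test = "kruskal-wallis"
            summaries[var] = table.groupby(group_col, observed=True)[var] \
                .median().to_dict()
        elif kind == "categorical":
            ct = pd.crosstab(table[group_col], table[var])
            res = stats.chi2_contingency(ct, correction=False)
            if (res.expected_freq == 0).any():
                raise ValueError(f"zero expected cell count for {var}")
            stat, p = float(res.statistic), float(res.pvalue)
            test = "chi-squared"
            summaries[var] = table.groupby(group_col, observed=True)[var] \
                .mean().to_dict()
        else:
            raise ValueError(f"unknown variable kind: {kind}")
        rows.append({"variable": var, "test": test, "statistic": float(stat),
                     "p": float(p), "significant": bool(p < ALPHA)})
    return GroupComparisonReport(results=pd.DataFrame(rows),
                                 group_summaries=summaries)


def anova_from_summary(ns, means, sds) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA from per-group (n, mean, sd) summaries.

    Between-group sum of squares from group means against the grand
    mean, within-group from (n-1)*sd^2; returns (F, (df1, df2), p).
    Lets printed cohort tables be tested without raw data.
    """
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if len(ns) < 2 or (ns < 2).any():
        raise ValueError("need >= 2 groups with n >= 2 each")
    if (sds < 0).any():
        raise ValueError("standard deviations must be non-negative")
    n_total = ns.sum()
    k = len(ns)
    grand = np.sum(ns * means) / n_total
    ss_between = np.sum(ns * (means - grand) ** 2)
    ss_within = np.sum((ns - 1) * sds ** 2)
    df1, df2 = k - 1, int(n_total - k)
    if ss_within == 0:
        return (np.inf if ss_between > 0 else 0.0), (df1, df2), \
            (0.0 if ss_between > 0 else 1.0)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return float(f), (df1, df2), p


@dataclass
class SurvivalCurves:
    curves: dict                 # group -> DataFrame(time, survival, ci_lower, ci_upper)
    logrank_statistic: float
    logrank_df: int
    logrank_p: float


def km_estimate(times, events, groups) -> SurvivalCurves:
    """Kaplan-Meier product-limit curves per group with 95% CIs
    (Greenwood-variance based), plus the log-rank comparison."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise ValueError("negative survival times")
    if events.sum() < 1:
        raise ValueError("need at least one event")
    curves = {}
    for g in np.unique(groups):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        ci = kmf.confidence_interval_survival_function_
        curves[g] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "ci_lower": np.clip(ci.iloc[:, 0].to_numpy(), 0.0, 1.0),
            "ci_upper": np.clip(ci.iloc[:, 1].to_numpy(), 0.0, 1.0),
        })
    stat, df, p = logrank(times, events, groups)
    return SurvivalCurves(curves=curves, logrank_statistic=stat,
                          logrank_df=df, logrank_p=p)


def logrank(times, events, groups) -> tuple[float, int, float]:
    """Multi-group log-rank test: (chi2 statistic, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    res = multivariate_logrank_test(times, groups, events)
    df = len(np.unique(groups)) - 1
    return float(res.test_statistic), df, float(res.p_value)


def prevalence_at(table: pd.DataFrame, days=(2, 7, 28),
                  outcomes=("ss", "vp", "mv"),
                  group_col: str = "phenotype") -> pd.DataFrame:
    """Per-phenotype support-flag rates at each horizon.

    Expects flag columns named ``<outcome><day>`` (e.g. ``ss7``); rates
    are flag means and are monotone non-decreasing in the horizon when
    the flags are.
    """
    rows = []
    for g, sub in table.groupby(group_col, observed=True):
        row = {"phenotype": g, "n": len(sub)}
        for out in outcomes:
            for day in days:
                col = f"{out}{day}"
                if col in sub:
                    row[col] = float(sub[col].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("phenotype")
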