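"""Factorial ANOVA, Bonferroni contrasts and parameter correlations.

The study's statistical machinery: every measured variable is modelled by
the full three-way factorial linear model

    value ~ sex + diet + time + sex:diet + sex:time + diet:time
            + sex:diet:time

with sex, diet and time as categorical factors ("independent measures"
ANOVA, no within-animal error stratum), F tests per term, and pairwise
group contrasts within each time point whose raw p-values are
Bonferroni-adjusted over the pairs compared at that time point.  Best-fit
model parameters (the unweighted-likelihood optima) are related to
pre-surgery measurements through Pearson correlations.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "FactorialFit",
    "RankDeficiencyError",
    "fit_factorial",
    "pairwise_contrasts",
    "correlate_params",
    "significance_stars",
]

logger = logging.getLogger(__name__)

FACTORS = ("sex", "diet", "time")


class RankDeficiencyError(ValueError):
    """Raised when empty design cells make the factorial model singular."""


@dataclass
class FactorialFit:
    """A fitted three-way factorial model with its ANOVA table."""

    response: str
    coefficients: pd.Series
    anova: pd.DataFrame  # index: term; columns include F, PR(>F)
    df_resid: float
    ss_type: str
    result: object  # statsmodels RegressionResults


def _check_cells(data: pd.DataFrame, response: str) -> None:
    for factor in FACTORS:
        if data[factor].nunique() < 2:
            raise ValueError(
                f"factor {factor!r} needs >= 2 observed levels for the "
                f"factorial model of {response!r}")
    counts = data.groupby(list(FACTORS), observed=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(data[f].unique()) for f in FACTORS], names=FACTORS)
    empty = full.difference(counts.index)
    if len(empty):
        raise RankDeficiencyError(
            f"empty design cells for {response!r}: "
            f"{[tuple(c) for c in empty[:10]]}"
            + (" ..." if len(empty) > 10 else ""))


def fit_factorial(
    data: pd.DataFrame,
    response: str,
    *,
    time_col: str = "t_hours",
    ss_type: str = "II",
) -> FactorialFit:
    """Least-squares fit of value ~ sex * diet * time with per-term F tests.

    ``data`` is long-format with columns sex, diet, ``time_col`` and
    ``response``; time is treated as categorical.  Type II sums of squares
    are the default; ``ss_type='III'`` switches to Type III with
    sum-to-zero contrasts.
    """
    work = data[["sex", "diet", time_col, response]].dropna().copy()
    work = work.rename(columns={time_col: "time"})
    work["time"] = work["time"].astype(float)
    _check_cells(work, response)
    if ss_type == "II":
        formula = f"{response} ~ C(sex) * C(diet) * C(time)"
    elif ss_type == "III":
        formula = (f"{response} ~ C(sex, Sum) * C(diet, Sum) "
                   f"* C(time, Sum)")
    else:
        raise ValueError(f"ss_type must be 'II' or 'III', got {ss_type!r}")
    fit = smf.ols(formula, data=work).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        anova = sm.stats.anova_lm(fit, typ=3 if ss_type == "III" else 2)
    return FactorialFit(response=response, coefficients=fit.params,
                        anova=anova, df_resid=float(fit.df_resid),
                        ss_type=ss_type, result=fit)


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def pairwise_contrasts(
    data: pd.DataFrame,
    response: str,
    *,
    time_col: str = "t_hours",
    group_cols: tuple[str, ...] = ("sex", "diet"),
) -> pd.DataFrame:
    """All pairwise group mean differences within each time point.

    Groups are the observed combinations of ``group_cols``.  Within each
    time point every group pair is compared by a pooled two-sample t test;
    the Bonferroni family is the number of pairs compared at that time
    point, so adjusted p = min(1, raw p * m).
    """
    work = data.dropna(subset=[response]).copy()
    work["_group"] = work[list(group_cols)].astype(str).agg(":".join, axis=1)
    rows = []
    for t, sub in work.groupby(time_col):
        groups = sorted(sub["_group"].unique())
        pairs = [(a, b) for a, b in itertools.combinations(groups, 2)]
        m = len(pairs)
        for a, b in pairs:
            va = sub.loc[sub["_group"] == a, response].to_numpy()
            vb = sub.loc[sub["_group"] == b, response].to_numpy()
            if va.size < 2 or vb.size < 2:
                est = float(va.mean() - vb.mean()) if va.size and vb.size \
                    else np.nan
                p = np.nan
                logger.warning("contrast %s vs %s at t=%s h: too few "
                               "observations", a, b, t)
            else:
                est = float(va.mean() - vb.mean())
                p = float(stats.ttest_ind(va, vb, equal_var=True).pvalue)
            p_adj = float(min(1.0, p * m)) if not np.isnan(p) else np.nan
            rows.append({
                "t_hours": t, "group1": a, "group2": b,
                "estimate": est, "n1": va.size, "n2": vb.size,
                "n_comparisons": m, "p_raw": p, "p_adj": p_adj,
                "signif": significance_stars(p_adj),
            })
    return pd.DataFrame(rows)


def correlate_params(
    fit_summaries: pd.DataFrame,
    pre_phx_measures: pd.DataFrame,
    *,
    params: tuple[str, ...] = ("best_M_unweighted", "best_Kcd_unweighted"),
) -> pd.DataFrame:
    """Pearson correlation of best-fit parameters with pre-PHx measures.

    Both inputs carry an ``animal_id`` column; ``pre_phx_measures`` holds
    one column per baseline measurement.  Pairs with fewer than three
    complete observations, or with a constant vector, are reported with
    missing R and a warning.
    """
    merged = fit_summaries.merge(pre_phx_measures, on="animal_id",
                                 how="inner")
    measures = [c for c in pre_phx_measures.columns if c != "animal_id"]
    rows = []
    for param in params:
        if param not in merged.columns:
            raise KeyError(f"column {param!r} missing from fit summaries")
        for measure in measures:
            sub = merged[[param, measure]].dropna()
            x = sub[param].to_numpy(dtype=float)
            y = sub[measure].to_numpy(dtype=float)
            r = p = np.nan
            if x.size < 3:
                logger.warning("correlation %s vs %s: only %d paired "
                               "observations", param, measure, x.size)
            elif np.ptp(x) == 0 or np.ptp(y) == 0:
                logger.warning("correlation %s vs %s: constant vector, "
                               "R undefined", param, measure)
            else:
                res = stats.pearsonr(x, y)
                r, p = float(res.statistic), float(res.pvalue)
            rows.append({"parameter": param, "measure": measure,
                         "n": int(x.size), "R": r, "p": p})
    return pd.DataFrame(rows)
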