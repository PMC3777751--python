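"""Group and severity statistics for the cohort biomarker table.

The battery mirrors how ROI biomarkers are analyzed in aging-continuum
cohorts: summary-statistic two-sample t-tests and chi-square tests for
demographics; an age-adjusted OLS with the four-level group factor coded by
three dummies (cognitively normal reference) plus planned per-group
contrasts with Cohen's d; partial (residual) correlations of biomarkers
with severity scores controlling age and education; and a hierarchical
regression forcing age and education in a first block, then letting the
perfusion and atrophy biomarkers compete stepwise (partial-F entry at
p < 0.05).  All tests are two-sided; missing values are dropped listwise
per analysis; no multiplicity correction is applied (planned comparisons).

Model fitting is delegated to statsmodels OLS; this module owns the design
construction, contrast bookkeeping, and the stepwise entry rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps


@dataclass
class Contrast:
    group: str
    t: float
    df: int
    p: float
    cohens_d: float  # raw-scale d, (group - reference) / pooled SD
    cohens_d_adjusted: float  # covariate-adjusted coefficient / pooled SD


@dataclass
class GroupModelResult:
    overall_F: float
    overall_df: tuple[int, int]
    overall_p: float
    group_F: float
    group_df: tuple[int, int]
    group_p: float
    contrasts: list[Contrast]
    n_used: int


@dataclass
class StepwiseResult:
    forced: dict[str, float]  # forced-variable standardized coefficients
    entered: list[tuple[str, float, float]]  # (name, standardized beta, entry p)
    final_F: float
    final_df: tuple[int, int]
    final_p: float
    n_used: int


# ---------------------------------------------------------------------------
# Summary-statistic tests


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test from printed summaries.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2; the t statistic is
    antisymmetric under swapping the two groups.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = sps.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def chi2_frequencies(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 frequency table, no continuity
    correction, df = 1."""
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any() or table.sum() == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in frequency table")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# Group model


def group_model(
    df: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age",),
    reference: str = "CN",
) -> GroupModelResult:
    """Age-adjusted group-effect regression with planned contrasts.

    OLS of the outcome on an intercept, dummies for each non-reference
    group, and the covariates.  Reports the overall model F, the partial F
    for the group-dummy block, and per-group contrasts versus the reference:
    the model t (covariate-adjusted) and Cohen's d from raw group
    means/pooled SD (negative d = lower outcome than the reference).
    """
    cols = list(dict.fromkeys([outcome, group_col, *covariates]))
    data = df[cols].dropna()
    glabels = data[group_col].astype(str)
    if reference not in set(glabels):
        raise ValueError(f"reference group {reference!r} missing from data")
    others = [g for g in pd.unique(glabels) if g != reference]
    if (glabels.value_counts() < 2).any():
        raise ValueError("each represented group needs at least 2 subjects")

    y = data[outcome].to_numpy(dtype=np.float64)
    n = len(y)
    dummies = np.column_stack(
        [(glabels == g).to_numpy(dtype=np.float64) for g in others]
    )
    cov = (
        data[list(covariates)].to_numpy(dtype=np.float64)
        if covariates
        else np.empty((n, 0))
    )
    X = np.column_stack([np.ones(n), dummies, cov])
    df_resid = n - X.shape[1]
    if np.ptp(y) == 0:
        # degenerate constant outcome: every coefficient is exactly zero
        contrasts = [
            Contrast(group=g, t=0.0, df=df_resid, p=1.0, cohens_d=0.0,
                     cohens_d_adjusted=0.0)
            for g in others
        ]
        return GroupModelResult(
            overall_F=0.0, overall_df=(X.shape[1] - 1, df_resid), overall_p=1.0,
            group_F=0.0, group_df=(len(others), df_resid), group_p=1.0,
            contrasts=contrasts, n_used=n,
        )
    res = sm.OLS(y, X).fit()
    df_resid = int(res.df_resid)

    # partial F for the dummy block (restricted model drops all dummies)
    X_ng = np.column_stack([np.ones(n), cov])
    res_ng = sm.OLS(y, X_ng).fit()
    group_F, group_p, group_df_num = res.compare_f_test(res_ng)

    contrasts = []
    ref_vals = y[(glabels == reference).to_numpy()]
    for j, g in enumerate(others):
        g_vals = y[(glabels == g).to_numpy()]
        n1, n2 = len(ref_vals), len(g_vals)
        pooled = np.sqrt(
            ((n1 - 1) * ref_vals.var(ddof=1) + (n2 - 1) * g_vals.var(ddof=1))
            / (n1 + n2 - 2)
        )
        d_raw = (g_vals.mean() - ref_vals.mean()) / pooled if pooled > 0 else 0.0
        d_adj = res.params[1 + j] / pooled if pooled > 0 else 0.0
        tval = float(res.tvalues[1 + j]) if np.isfinite(res.tvalues[1 + j]) else 0.0
        pval = float(res.pvalues[1 + j]) if np.isfinite(res.pvalues[1 + j]) else 1.0
        contrasts.append(
            Contrast(
                group=g,
                t=tval,
                df=df_resid,
                p=pval,
                cohens_d=float(d_raw),
                cohens_d_adjusted=float(d_adj),
            )
        )
    overall_F = float(res.fvalue) if np.isfinite(res.fvalue) else 0.0
    overall_p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
    return GroupModelResult(
        overall_F=overall_F,
        overall_df=(int(res.df_model), df_resid),
        overall_p=overall_p,
        group_F=float(group_F),
        group_df=(int(group_df_num), df_resid),
        group_p=float(group_p),
        contrasts=contrasts,
        n_used=n,
    )


# ---------------------------------------------------------------------------
# Partial correlation


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """Partial Pearson correlation by the residual method.

    x and y are each regressed on [intercept, covariates]; the correlation
    of the residuals is returned with a two-sided p from t with
    df = n - k - 2 (k covariates).  With no covariates this reduces to the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        Z = np.column_stack([np.ones(n), covariates])
        k = covariates.shape[1]
    if n <= k + 2:
        raise ValueError("partial correlation requires n > k + 2")
    rx = sm.OLS(x, Z).fit().resid
    ry = sm.OLS(y, Z).fit().resid
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("degenerate (constant) residuals")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1 - r**2))
    p = float(2 * sps.t.sf(abs(t), df))
    return r, p


# ---------------------------------------------------------------------------
# Hierarchical stepwise regression


def stepwise_hierarchical(
    df: pd.DataFrame,
    outcome: str,
    forced: tuple[str, ...] = ("age", "education"),
    candidates: tuple[str, ...] = ("meta_roi_cbf", "hippo_norm"),
    p_enter: float = 0.05,
) -> StepwiseResult:
    """Two-block hierarchical regression with stepwise candidate entry.

    Block 1 forces the covariates in; block 2 admits, one at a time, the
    candidate with the smallest partial-F p-value below ``p_enter`` until
    none qualifies (for a single added regressor the partial F equals the
    squared coefficient t, so the coefficient p is the entry p).
    Coefficients are standardized betas (all variables z-scored).
    Constant candidates are excluded with a warning.
    """
    cols = list(dict.fromkeys([outcome, *forced, *candidates]))
    data = df[cols].dropna()
    n = len(data)
    usable = []
    for c in candidates:
        if data[c].std() == 0:
            warnings.warn(f"candidate {c!r} is constant; excluded")
        else:
            usable.append(c)

    def z(col: str) -> np.ndarray:
        v = data[col].to_numpy(dtype=np.float64)
        s = v.std(ddof=1)
        return (v - v.mean()) / s if s > 0 else np.zeros(n)

    yz = z(outcome)
    current = np.column_stack([np.ones(n)] + [z(c) for c in forced])
    remaining = list(usable)
    order: list[str] = []
    entry_p: dict[str, float] = {}
    while remaining:
        best = None
        for c in remaining:
            Xc = np.column_stack([current, z(c)])
            pc = float(sm.OLS(yz, Xc).fit().pvalues[-1])
            if best is None or pc < best[1]:
                best = (c, pc)
        if best is None or not best[1] < p_enter:
            break
        name, pc = best
        entry_p[name] = pc
        current = np.column_stack([current, z(name)])
        remaining.remove(name)
        order.append(name)

    res = sm.OLS(yz, current).fit()
    forced_coefs = {c: float(res.params[1 + i]) for i, c in enumerate(forced)}
    entered = [
        (name, float(res.params[1 + len(forced) + i]), entry_p[name])
        for i, name in enumerate(order)
    ]
    final_F = float(res.fvalue) if np.isfinite(res.fvalue) else 0.0
    final_p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
    return StepwiseResult(
        forced=forced_coefs,
        entered=entered,
        final_F=final_F,
        final_df=(int(res.df_model), int(res.df_resid)),
        final_p=final_p,
        n_used=n,
    )
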