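"""Descriptive statistics and adjusted group-difference tests.

One-way ANOVA (raw data or summary statistics), Pearson chi-squared for
proportions, age/sex-adjusted ANCOVA with Bonferroni post hoc contrasts,
and Welch t-tests by APOE e4 carrier status. Summary-statistic entry
points exist so that tests printed in publications (means, SDs, group
sizes) can be reproduced exactly without subject-level data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

ALPHA = 0.05  # two-tailed significance level used throughout


@dataclass(frozen=True)
class StatTestResult:
    test_name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_direction: float | None = None
    group_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class PosthocTable:
    """All pairwise covariate-adjusted contrasts with Bonferroni correction."""

    rows: tuple[dict, ...]
    n_comparisons: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(list(self.rows))


def _as_groups(values: Sequence[float], groups: Sequence) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    return {g: values[groups == g] for g in pd.unique(groups)}


def anova_oneway(values: Sequence[float], groups: Sequence) -> StatTestResult:
    """Classical one-way ANOVA F-test on subject-level data.

    Computes the between/within sum-of-squares decomposition via the
    summary-statistic path, so raw-data and summary entry points agree
    identically.
    """
    by_group = _as_groups(values, groups)
    if len(by_group) < 2:
        raise ValueError("ANOVA requires at least 2 groups")
    for g, v in by_group.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    means = [float(np.mean(v)) for v in by_group.values()]
    sds = [float(np.std(v, ddof=1)) for v in by_group.values()]
    ns = [int(v.size) for v in by_group.values()]
    res = anova_oneway_from_stats(means, sds, ns)
    return StatTestResult(
        test_name="anova_oneway",
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        group_labels=tuple(str(g) for g in by_group),
    )


def anova_oneway_from_stats(
    means: Sequence[float], sds: Sequence[float], ns: Sequence[int]
) -> StatTestResult:
    """One-way ANOVA from per-group means, SDs and sizes.

    F = [sum n_i (m_i - m)^2 / (k-1)] / [sum (n_i - 1) s_i^2 / (N-k)]
    with the grand mean m weighted by group size.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if not (means.size == sds.size == ns.size) or means.size < 2:
        raise ValueError("need matching means/sds/ns for >= 2 groups")
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    k, N = means.size, float(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1.0, N - k
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else np.inf
    else:
        f = (ssb / df1) / (ssw / df2)
    p = 1.0 if f == 0.0 else float(stats.f.sf(f, df1, df2))
    return StatTestResult(
        test_name="anova_oneway", statistic=float(f), df=(df1, df2), p_value=p
    )


def counts_from_percentages(
    percentages: Sequence[float], ns: Sequence[int], tol: float = 0.51
) -> np.ndarray:
    """Reconstruct integer category counts from printed percentages.

    Errors if the nearest integer count, converted back to a percentage,
    differs from the printed one by more than ``tol`` percentage points
    (guards against mismatched or mistyped tables).
    """
    percentages = np.asarray(percentages, dtype=float)
    ns = np.asarray(ns, dtype=float)
    raw = percentages / 100.0 * ns
    counts = np.round(raw)
    off = np.abs(percentages - 100.0 * counts / ns)
    if np.any(off > tol):
        j = int(np.argmax(off))
        raise ValueError(
            f"percentage {percentages[j]}% of n={int(ns[j])} implies a "
            f"non-integer count ({raw[j]:.2f})"
        )
    return counts.astype(int)


def chi_squared_proportions(counts: np.ndarray | Sequence[Sequence[int]]) -> StatTestResult:
    """Pearson chi-squared on a group x category contingency table.

    No continuity correction; df = (rows-1)(cols-1). All expected counts
    must be positive.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero marginal")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return StatTestResult(
        test_name="chi_squared", statistic=float(chi2), df=(float(dof),), p_value=float(p)
    )


def _ancova_design(
    values: Sequence[float],
    groups: Sequence,
    covariates: pd.DataFrame | np.ndarray | None,
):
    y = np.asarray(values, dtype=float)
    groups = pd.Series(np.asarray(groups), name="group").astype(str)
    if len(y) != len(groups):
        raise ValueError("values and groups must have equal length")
    dummies = pd.get_dummies(groups, prefix="group", drop_first=True, dtype=float)
    if covariates is None:
        cov = pd.DataFrame(index=dummies.index)
    else:
        cov = pd.DataFrame(np.asarray(covariates, dtype=float), index=dummies.index)
        cov.columns = [f"cov_{c}" for c in (covariates.columns if isinstance(covariates, pd.DataFrame) else range(cov.shape[1]))]
        # constant covariates carry no information beyond the intercept
        cov = cov.loc[:, cov.std(axis=0) > 0]
    X_full = pd.concat([dummies, cov], axis=1)
    X_full.insert(0, "const", 1.0)
    return y, groups, dummies, cov, X_full


def ancova_adjusted(
    values: Sequence[float],
    groups: Sequence,
    covariates: pd.DataFrame | np.ndarray | None,
) -> tuple[StatTestResult, dict[str, float]]:
    """ANCOVA: value ~ group + covariates; partial F-test for group.

    Returns the group-factor F-test (full vs covariate-only reduced
    model) and per-group adjusted means evaluated at the covariate means.
    """
    y, groups, dummies, cov, X_full = _ancova_design(values, groups, covariates)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("ANCOVA requires at least 2 groups")
    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        raise ValueError(
            f"rank-deficient ANCOVA design: {X_full.shape[1]} columns, rank {rank}; "
            f"columns {list(X_full.columns)}"
        )
    full = sm.OLS(y, X_full).fit()
    X_red = pd.concat([cov], axis=1)
    X_red.insert(0, "const", 1.0)
    reduced = sm.OLS(y, X_red).fit()
    df1 = full.df_model - reduced.df_model
    df2 = full.df_resid
    f = ((reduced.ssr - full.ssr) / df1) / (full.ssr / df2)
    p = float(stats.f.sf(f, df1, df2))

    # adjusted means: fitted value per group at the covariate means
    cov_means = cov.mean(axis=0)
    adjusted: dict[str, float] = {}
    for g in labels:
        row = {"const": 1.0, **{c: 0.0 for c in dummies.columns}, **cov_means.to_dict()}
        col = f"group_{g}"
        if col in row:
            row[col] = 1.0
        x = pd.Series(row)[X_full.columns]
        adjusted[g] = float(x @ full.params)
    result = StatTestResult(
        test_name="ancova_group",
        statistic=float(f),
        df=(float(df1), float(df2)),
        p_value=p,
        group_labels=tuple(labels),
    )
    return result, adjusted


def bonferroni_posthoc(
    values: Sequence[float],
    groups: Sequence,
    covariates: pd.DataFrame | np.ndarray | None,
) -> PosthocTable:
    """All pairwise adjusted-mean contrasts from the ANCOVA fit.

    Raw p-values come from t-tests on the contrast of group coefficients;
    the Bonferroni-adjusted p is min(1, raw * k(k-1)/2).
    """
    y, groups, dummies, cov, X_full = _ancova_design(values, groups, covariates)
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("post hoc contrasts require at least 2 groups")
    full = sm.OLS(y, X_full).fit()
    n_comp = len(labels) * (len(labels) - 1) // 2
    cols = list(X_full.columns)

    def coef_vector(g: str) -> np.ndarray:
        v = np.zeros(len(cols))
        col = f"group_{g}"
        if col in cols:
            v[cols.index(col)] = 1.0
        return v

    rows = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1 :]:
            contrast = coef_vector(gi) - coef_vector(gj)
            test = full.t_test(contrast)
            raw = float(test.pvalue)
            adj = min(1.0, raw * n_comp)
            rows.append(
                {
                    "group_a": gi,
                    "group_b": gj,
                    "adjusted_mean_difference": float(test.effect[0]),
                    "p_raw": raw,
                    "p_bonferroni": adj,
                    "significant": adj < ALPHA,
                }
            )
    return PosthocTable(rows=tuple(rows), n_comparisons=n_comp)


def ttest_by_carrier(
    values: Sequence[float], carrier_flags: Sequence[bool]
) -> StatTestResult:
    """Welch two-sample t-test of a biomarker by APOE e4 carriage.

    Unequal-variance (Welch) with Satterthwaite df; two-tailed. The
    effect direction is mean(carriers) - mean(non-carriers).
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(carrier_flags, dtype=bool)
    a, b = values[flags], values[~flags]
    if a.size < 2 or b.size < 2:
        raise ValueError("both carrier strata need n >= 2")
    res = ttest_from_stats(
        float(np.mean(a)), float(np.std(a, ddof=1)), a.size,
        float(np.mean(b)), float(np.std(b, ddof=1)), b.size,
    )
    return StatTestResult(
        test_name="welch_t_carrier",
        statistic=res.statistic,
        df=res.df,
        p_value=res.p_value,
        effect_direction=float(np.mean(a) - np.mean(b)),
        group_labels=("carrier", "non_carrier"),
    )


def ttest_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> StatTestResult:
    """Welch t-test from summary statistics (mean, SD, n per stratum)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both strata need n >= 2")
    if sd1 == 0 and sd2 == 0 and mean1 == mean2:
        # identical degenerate strata: no evidence of a difference
        return StatTestResult(
            test_name="welch_t", statistic=0.0, df=(float(n1 + n2 - 2),), p_value=1.0,
            effect_direction=0.0,
        )
    t, p = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=False
    )
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return StatTestResult(
        test_name="welch_t",
        statistic=float(t),
        df=(float(df),),
        p_value=float(p),
        effect_direction=mean1 - mean2,
    )


def descriptive_table(df: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Publication-style descriptive table: mean +/- SD per group plus tests.

    Continuous variables get a one-way ANOVA p; the sex proportion gets a
    chi-squared p.
    """
    groups = sorted(df[group_col].unique())
    rows = []
    continuous = ["age", "education", "ptau217", "abeta42", "ratio", "gfap"]
    if "global_suvr" in df.columns:
        continuous.append("global_suvr")
    for var in continuous:
        sub = df[[group_col, var]].dropna()
        cells = {
            g: f"{sub.loc[sub[group_col] == g, var].mean():.2f} ± "
            f"{sub.loc[sub[group_col] == g, var].std(ddof=1):.2f}"
            for g in groups
        }
        try:
            p = anova_oneway(sub[var].to_numpy(), sub[group_col].to_numpy()).p_value
            cells["p_value"] = f"{p:.3g}"
        except ValueError:
            cells["p_value"] = "NA"
        rows.append({"variable": var, **cells})
    if "sex" in df.columns:
        table = np.array(
            [
                [
                    int((df.loc[df[group_col] == g, "sex"] == "F").sum()),
                    int((df.loc[df[group_col] == g, "sex"] == "M").sum()),
                ]
                for g in groups
            ]
        )
        cells = {
            g: f"{100.0 * table[i, 0] / table[i].sum():.1f}% F" for i, g in enumerate(groups)
        }
        cells["p_value"] = f"{chi_squared_proportions(table).p_value:.3g}"
        rows.append({"variable": "sex_female", **cells})
    return pd.DataFrame(rows)
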