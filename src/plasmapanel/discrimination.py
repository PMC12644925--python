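"""ROC discrimination of plasma biomarkers for amyloid-PET positivity.

Empirical AUC by the Mann-Whitney pair-counting statistic (ties count
one half), DeLong structural-component 95% confidence intervals, and
covariate-augmented scores from a logistic model of amyloid status on a
biomarker plus APOE e4 carriage. Subgroup analyses run the identical
machinery within the cognitively unimpaired or impaired stratum.

The amyloid reference standard is Centiloid > 20; subjects lacking a
centiloid value are excluded from discrimination analyses rather than
imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
import statsmodels.api as sm

from plasmapanel.synthetic_cohort import (
    CENTILOID_POSITIVE,
    CU_GROUPS,
    IMPAIRED_GROUPS,
    Cohort,
)


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC summary for one score definition."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    curve: np.ndarray  # (k, 2) array of (FPR, TPR), ordered
    score_spec: str  # "raw" or "logistic+apoe"

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.auc <= self.ci_high + 1e-12):
            raise ValueError("AUC must lie within its confidence interval")


def _check_labels(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC requires both a positive and a negative class")
    return labels, ~labels


def amyloid_labels(centiloid: np.ndarray, threshold: float = CENTILOID_POSITIVE) -> np.ndarray:
    """Binary amyloid reference: positive iff centiloid > threshold."""
    return np.asarray(centiloid, dtype=float) > threshold


def auc_mann_whitney(scores, labels) -> float:
    """Empirical AUC by pair counting with the half-tie convention.

    AUC = [#(pos, neg) pairs with score_pos > score_neg + 0.5 * ties]
    / (n_pos * n_neg), computed via midranks (equivalent, O(n log n)).
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_labels(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_components(scores: np.ndarray, labels) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus DeLong structural components V10 (per positive), V01 (per negative)."""
    pos_mask, neg_mask = _check_labels(labels)
    x = np.asarray(scores, dtype=float)[pos_mask]
    y = np.asarray(scores, dtype=float)[neg_mask]
    m, n = x.size, y.size
    # midrank-based placements
    all_scores = np.concatenate([x, y])
    r_all = stats.rankdata(all_scores)
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (r_all[:m] - r_x) / n  # P(Y < x_i) + 0.5 P(Y = x_i)
    v01 = 1.0 - (r_all[m:] - r_y) / m  # P(x > y_j) + 0.5 ties
    return float(auc), v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong sampling variance of the empirical AUC (always >= 0)."""
    auc, v10, v01 = _delong_components(np.asarray(scores, float), labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc_ci_delong(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong normal-approximation confidence interval, clipped to [0, 1]."""
    pos_mask, neg_mask = _check_labels(labels)
    if pos_mask.sum() < 2 or neg_mask.sum() < 2:
        raise ValueError("DeLong CI needs >= 2 subjects in each class")
    auc = auc_mann_whitney(scores, labels)
    se = np.sqrt(delong_variance(scores, labels))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return float(np.clip(auc - z * se, 0.0, 1.0)), float(np.clip(auc + z * se, 0.0, 1.0))


def logistic_augmented_score(biomarker, apoe_flags, labels) -> tuple[np.ndarray, bool]:
    """Fitted P(amyloid+) from a logistic model: label ~ biomarker + APOE e4.

    Returns (scores, used_fallback). On separation or non-convergence the
    function warns and falls back to the raw biomarker ranking (flagged
    with used_fallback=True) instead of returning unstable coefficients.
    """
    x = np.asarray(biomarker, dtype=float)
    a = np.asarray(apoe_flags, dtype=float)
    y = np.asarray(labels).astype(float)
    if y.all() or not y.any():
        raise ValueError("logistic fit requires both outcome classes")
    cols = [c for c in (x, a) if np.ptp(c) > 0]  # drop constants (e.g. all-carrier)
    if not cols:
        return x.copy(), True
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-8)
        if not fit.mle_retvals.get("converged", False) or np.abs(fit.params).max() > 1e6:
            raise RuntimeError("logistic fit did not converge")
    except Exception:
        warnings.warn(
            "logistic fit failed (separation or non-convergence); "
            "falling back to the raw biomarker ranking",
            RuntimeWarning,
            stacklevel=2,
        )
        return x.copy(), True
    return np.asarray(fit.predict(X)), False


def roc_analysis(
    scores,
    labels,
    score_spec: str = "raw",
) -> RocResult:
    """Full empirical ROC: AUC, DeLong 95% CI and the (FPR, TPR) curve."""
    scores = np.asarray(scores, dtype=float)
    pos_mask, neg_mask = _check_labels(labels)
    fpr, tpr, _ = roc_curve(np.asarray(labels).astype(int), scores)
    lo, hi = auc_ci_delong(scores, labels)
    return RocResult(
        auc=auc_mann_whitney(scores, labels),
        ci_low=lo,
        ci_high=hi,
        n_pos=int(pos_mask.sum()),
        n_neg=int(neg_mask.sum()),
        curve=np.column_stack([fpr, tpr]),
        score_spec=score_spec,
    )


def subgroup_roc(
    cohort: Cohort,
    marker: str,
    stratum: str = "all",
    with_apoe: bool = False,
    cl_threshold: float = CENTILOID_POSITIVE,
) -> RocResult:
    """ROC for one marker within a cognitive stratum.

    stratum: "all", "CU" (amyloid-negative + positive cognitively
    unimpaired) or "impaired" (MCI + AD dementia). Subjects without a
    centiloid value are dropped. With ``with_apoe`` the score is the
    fitted probability from the logistic biomarker + APOE e4 model.
    """
    df = cohort.df
    if stratum == "CU":
        df = df[df["group"].isin(CU_GROUPS)]
    elif stratum == "impaired":
        df = df[df["group"].isin(IMPAIRED_GROUPS)]
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}; use all, CU or impaired")
    df = df.dropna(subset=["centiloid", marker])
    labels = amyloid_labels(df["centiloid"].to_numpy(), cl_threshold)
    if labels.all() or not labels.any():
        raise ValueError(f"stratum {stratum!r} contains a single amyloid class")
    if with_apoe:
        scores, fell_back = logistic_augmented_score(
            df[marker].to_numpy(), df["apoe_e4_carrier"].to_numpy(), labels
        )
        spec = "raw(fallback)" if fell_back else "logistic+apoe"
    else:
        scores, spec = df[marker].to_numpy(), "raw"
    return roc_analysis(scores, labels, score_spec=spec)


def roc_summary_table(
    cohort: Cohort,
    markers=("ptau217", "abeta42", "ratio", "gfap"),
    strata=("all", "CU", "impaired"),
    cl_threshold: float = CENTILOID_POSITIVE,
) -> pd.DataFrame:
    """Per-marker, per-stratum AUC table with and without the APOE covariate."""
    rows = []
    for stratum in strata:
        for marker in markers:
            for with_apoe in (False, True):
                res = subgroup_roc(
                    cohort, marker, stratum=stratum, with_apoe=with_apoe,
                    cl_threshold=cl_threshold,
                )
                rows.append(
                    {
                        "marker": marker,
                        "stratum": stratum,
                        "score": res.score_spec,
                        "auc": res.auc,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n_pos": res.n_pos,
                        "n_neg": res.n_neg,
                    }
                )
    return pd.DataFrame(rows)
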