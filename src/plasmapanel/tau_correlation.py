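"""Partial correlations between plasma biomarkers and regional tau PET.

Residual-based partial correlation: both variables are regressed on an
intercept plus covariates (age and sex by default) with ordinary least
squares, and the Pearson correlation of the residual vectors is tested
with df = n - 2 - k. Regions are grouped and ordered by Braak-stage
topography (I-II mesial temporal, III-IV meta-temporal/associative,
V-VI isocortical, then global composites), and each cell carries a
raw-p significance tier (* < 0.05, ** < 0.01, *** < 0.001) without
multiplicity correction, matching common heatmap reporting practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from plasmapanel.synthetic_cohort import (
    CU_GROUPS,
    IMPAIRED_GROUPS,
    Cohort,
    default_braak_regions,
)

STAGE_ORDER = ("braak_1_2", "braak_3_4", "braak_5_6", "global")
BIOMARKER_ROWS = ("ptau217", "abeta42", "ratio", "gfap")


@dataclass(frozen=True)
class BraakMapping:
    """Region name -> Braak stage group; every region maps exactly once."""

    region_stage: Mapping[str, str]

    def __post_init__(self) -> None:
        if not self.region_stage:
            raise ValueError("Braak mapping must cover at least one region")
        bad = {s for s in self.region_stage.values() if s not in STAGE_ORDER}
        if bad:
            raise ValueError(f"unknown stage groups {sorted(bad)}; expected {STAGE_ORDER}")

    def ordered_regions(self) -> tuple[str, ...]:
        return tuple(
            r
            for stage in STAGE_ORDER
            for r in self.region_stage
            if self.region_stage[r] == stage
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BraakMapping":
        """Build from a two-column (region, stage_group) table."""
        return cls(dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str))))


def default_braak_mapping() -> BraakMapping:
    return BraakMapping(default_braak_regions())


def significance_tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class TauCorrelationMatrix:
    """Biomarkers x Braak-ordered regions partial-correlation results."""

    r: pd.DataFrame  # rows biomarkers, cols regions
    p: pd.DataFrame
    n: pd.DataFrame
    tiers: pd.DataFrame
    region_stage: Mapping[str, str] = field(default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for marker in self.r.index:
            for region in self.r.columns:
                rows.append(
                    {
                        "biomarker": marker,
                        "region": region,
                        "stage": self.region_stage.get(region, ""),
                        "r": self.r.loc[marker, region],
                        "p_value": self.p.loc[marker, region],
                        "n": self.n.loc[marker, region],
                        "tier": self.tiers.loc[marker, region],
                    }
                )
        return pd.DataFrame(rows)


def residualize(values, covariates) -> np.ndarray:
    """OLS residuals of values on an intercept plus covariate columns."""
    y = np.asarray(values, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.size <= X.shape[1] + 1:
        raise ValueError(
            f"need n > k + 1 observations (n={y.size}, k={X.shape[1]})"
        )
    keep = np.ptp(X, axis=0) > 0  # constant columns duplicate the intercept
    X = X[:, keep]
    design = np.column_stack([np.ones(y.size), X])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def partial_corr(x, y, covariates) -> tuple[float, float, int]:
    """Partial Pearson correlation of x and y given covariates.

    Correlates the two OLS residual vectors; the p-value uses
    t = r sqrt(df / (1 - r^2)) with df = n - 2 - k, two-tailed.
    Returns (r, p, n).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    k = X.shape[1]
    n = x.size
    if n <= k + 2:
        raise ValueError(f"partial correlation needs n > k + 2 (n={n}, k={k})")
    rx = residualize(x, X)
    ry = residualize(y, X)
    if np.allclose(rx, 0.0) or np.allclose(ry, 0.0):
        raise ValueError("zero-variance residuals: a variable is fully explained by covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clamped = min(max(r, -1.0), 1.0)
    if abs(r_clamped) >= 1.0:
        p = 0.0
    else:
        t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p, n


def _sex_numeric(sex: pd.Series) -> np.ndarray:
    # female = 1, male = 0 (binary adjustment covariate)
    return (sex.astype(str) == "F").astype(float).to_numpy()


def braak_heatmap(
    cohort: Cohort,
    mapping: BraakMapping | None = None,
    stratum: str = "all",
    biomarkers: Sequence[str] = BIOMARKER_ROWS,
) -> TauCorrelationMatrix:
    """Age/sex-adjusted partial correlations, biomarkers x tau regions.

    Runs one partial correlation per biomarker-region cell over the
    subjects possessing that region's SUVR (pairwise deletion; per-cell
    n is reported). Columns are ordered Braak I-II, III-IV, V-VI, then
    global. stratum selects all tau subjects, the cognitively
    unimpaired, or the impaired.
    """
    if mapping is None:
        mapping = default_braak_mapping()
    df = cohort.df
    if stratum == "CU":
        df = df[df["group"].isin(CU_GROUPS)]
    elif stratum == "impaired":
        df = df[df["group"].isin(IMPAIRED_GROUPS)]
    elif stratum != "all":
        raise ValueError(f"unknown stratum {stratum!r}")

    regions = mapping.ordered_regions()
    missing_cols = [r for r in regions if f"tau_{r}" not in df.columns]
    if missing_cols:
        raise ValueError(
            f"cohort has no tau columns for mapped regions {missing_cols}"
        )
    has_tau = df[[f"tau_{r}" for r in regions]].notna().any(axis=1)
    df = df[has_tau]
    k = 2  # age + sex
    if len(df) < k + 3:
        raise ValueError(
            f"stratum {stratum!r} has {len(df)} tau subjects; need >= {k + 3}"
        )

    r_mat = pd.DataFrame(index=list(biomarkers), columns=list(regions), dtype=float)
    p_mat = r_mat.copy()
    n_mat = pd.DataFrame(index=list(biomarkers), columns=list(regions), dtype=int)
    tier_mat = pd.DataFrame(index=list(biomarkers), columns=list(regions), dtype=object)
    for region in regions:
        col = f"tau_{region}"
        sub = df.dropna(subset=[col])
        cov = np.column_stack([sub["age"].to_numpy(float), _sex_numeric(sub["sex"])])
        for marker in biomarkers:
            r, p, n = partial_corr(sub[marker].to_numpy(float), sub[col].to_numpy(float), cov)
            r_mat.loc[marker, region] = r
            p_mat.loc[marker, region] = p
            n_mat.loc[marker, region] = n
            tier_mat.loc[marker, region] = significance_tier(p)
    return TauCorrelationMatrix(
        r=r_mat, p=p_mat, n=n_mat, tiers=tier_mat,
        region_stage=dict(mapping.region_stage),
    )


def plot_heatmap(matrix: TauCorrelationMatrix, path: str) -> None:
    """Optional rendered heatmap (r values annotated with tiers)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(0.9 * len(matrix.r.columns) + 2, 0.6 * len(matrix.r.index) + 2)
    )
    data = matrix.r.astype(float).to_numpy()
    im = ax.imshow(data, cmap="RdBu_r", vmin=-1, vmax=1, aspect="auto")
    ax.set_xticks(range(len(matrix.r.columns)))
    ax.set_xticklabels(matrix.r.columns, rotation=90)
    ax.set_yticks(range(len(matrix.r.index)))
    ax.set_yticklabels(matrix.r.index)
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            tier = matrix.tiers.iloc[i, j]
            label = f"{data[i, j]:.2f}" + ("" if tier == "ns" else tier)
            ax.text(j, i, label, ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="partial r (age/sex adjusted)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
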