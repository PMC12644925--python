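"""Dual-cutoff / indeterminate-zone classification framework.

Derives a lower and an upper biomarker threshold by constrained search:
subjects above the upper cutoff are called positive, below the lower
cutoff negative, and in between indeterminate. Among threshold pairs
meeting predictive-value and likelihood-ratio targets (PPV >= 0.90,
NPV >= 0.90, PLR > 5, NLR < 0.1 by default), the pair minimizing the
indeterminate-zone fraction is selected. Confidence intervals come from
a nonparametric bootstrap over subjects.

Likelihood ratios use full-class denominators (the three zone
probabilities within each disease class sum to one), which is the only
convention under which an "intermediate PLR" is coherent:

    PLR  = P(positive zone | D+) / P(positive zone | D-)
    NLR  = P(negative zone | D+) / P(negative zone | D-)
    iPLR = P(intermediate   | D+) / P(intermediate   | D-)

The candidate threshold grid is the set of midpoints between consecutive
order statistics plus one sentinel below the minimum and one above the
maximum: any other threshold induces an identical partition of the
observed sample, so the grid search is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np


@dataclass(frozen=True)
class CutoffConstraints:
    """Performance targets the selected threshold pair must meet.

    PPV/NPV are compared with >=, likelihood ratios strictly (> / <).
    """

    min_ppv: float = 0.90
    min_npv: float = 0.90
    min_plr: float = 5.0
    max_nlr: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_ppv <= 1.0 and 0.0 <= self.min_npv <= 1.0):
            raise ValueError("min_ppv and min_npv must be in [0, 1]")
        if self.min_plr < 0 or self.max_nlr <= 0:
            raise ValueError("min_plr must be >= 0 and max_nlr > 0")


@dataclass(frozen=True)
class ThreeZoneCounts:
    """Zone occupancy: (a, b, c) for D+ and (d, e, f) for D-.

    a/d above the upper cutoff, b/e intermediate, c/f below the lower.
    """

    a: int
    b: int
    c: int
    d: int
    e: int
    f: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d, self.e, self.f) < 0:
            raise ValueError("zone counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d + self.e + self.f

    @property
    def n_pos(self) -> int:
        return self.a + self.b + self.c

    @property
    def n_neg(self) -> int:
        return self.d + self.e + self.f


@dataclass(frozen=True)
class ClassificationMetrics:
    """Three-zone classification metrics; NaN fields carry a reason."""

    ppv: float
    npv: float
    sens_pos: float
    spec_neg: float
    plr: float
    nlr: float
    intermediate_plr: float
    intermediate_fraction: float
    counts: ThreeZoneCounts
    undefined: Mapping[str, str] = field(default_factory=dict)
    ci: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "ppv": self.ppv,
            "npv": self.npv,
            "sens_pos": self.sens_pos,
            "spec_neg": self.spec_neg,
            "plr": self.plr,
            "nlr": self.nlr,
            "intermediate_plr": self.intermediate_plr,
            "intermediate_fraction": self.intermediate_fraction,
        }


@dataclass(frozen=True)
class DualCutoffResult:
    lower: float
    upper: float
    feasible: bool
    metrics: ClassificationMetrics
    n_violated: int = 0
    bootstrap: Mapping | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower cutoff must be <= upper cutoff")


def classify_three_zone(values, lower: float, upper: float) -> np.ndarray:
    """Assign each value to a zone: above upper -> "positive", below
    lower -> "negative", otherwise (boundaries included) "intermediate".
    """
    if lower > upper:
        raise ValueError(f"lower cutoff {lower} exceeds upper cutoff {upper}")
    values = np.asarray(values, dtype=float)
    zones = np.full(values.shape, "intermediate", dtype=object)
    zones[values > upper] = "positive"
    zones[values < lower] = "negative"
    return zones


def three_zone_counts(zones, labels) -> ThreeZoneCounts:
    zones = np.asarray(zones, dtype=object)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("three-zone counting requires both disease classes")
    pos, neg = labels, ~labels
    return ThreeZoneCounts(
        a=int(((zones == "positive") & pos).sum()),
        b=int(((zones == "intermediate") & pos).sum()),
        c=int(((zones == "negative") & pos).sum()),
        d=int(((zones == "positive") & neg).sum()),
        e=int(((zones == "intermediate") & neg).sum()),
        f=int(((zones == "negative") & neg).sum()),
    )


def _ratio(num: float, den: float, name: str, undefined: dict) -> float:
    if den == 0:
        if num == 0:
            undefined[name] = "0/0: no subjects in either zone"
        else:
            undefined[name] = "zero denominator"
            return float(np.inf)
        return float(np.nan)
    return num / den


def metrics_from_counts(counts: ThreeZoneCounts) -> ClassificationMetrics:
    """All three-zone metrics from zone occupancy counts.

    Undefined quantities (zero denominators) are reported as NaN (or
    +inf for a likelihood ratio whose reference-class probability is
    zero but whose disease-class probability is not) with an explanatory
    reason — never silently dropped.
    """
    a, b, c, d, e, f = counts.a, counts.b, counts.c, counts.d, counts.e, counts.f
    npos, nneg = counts.n_pos, counts.n_neg
    if npos == 0 or nneg == 0:
        raise ValueError("metrics require both disease classes")
    undefined: dict[str, str] = {}
    ppv = a / (a + d) if (a + d) > 0 else float(np.nan)
    if (a + d) == 0:
        undefined["ppv"] = "no subject called positive"
    npv = f / (c + f) if (c + f) > 0 else float(np.nan)
    if (c + f) == 0:
        undefined["npv"] = "no subject called negative"
    sens = a / npos
    spec = f / nneg
    plr = _ratio(a / npos, d / nneg, "plr", undefined)
    nlr = _ratio(c / npos, f / nneg, "nlr", undefined)
    iplr = _ratio(b / npos, e / nneg, "intermediate_plr", undefined)
    return ClassificationMetrics(
        ppv=float(ppv),
        npv=float(npv),
        sens_pos=float(sens),
        spec_neg=float(spec),
        plr=float(plr),
        nlr=float(nlr),
        intermediate_plr=float(iplr),
        intermediate_fraction=float((b + e) / counts.n),
        counts=counts,
        undefined=undefined,
    )


def classification_metrics(zones, labels) -> ClassificationMetrics:
    """Three-zone metrics from per-subject zones and disease labels."""
    return metrics_from_counts(three_zone_counts(zones, labels))


def candidate_thresholds(values) -> np.ndarray:
    """Midpoints of consecutive sorted unique values plus +/- sentinels."""
    u = np.unique(np.asarray(values, dtype=float))
    if u.size == 0:
        raise ValueError("no values to threshold")
    span = max(1.0, abs(u[0]), abs(u[-1]))
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate([[u[0] - 0.01 * span], mids, [u[-1] + 0.01 * span]])


def _violations_and_keys(
    cp: np.ndarray,
    cn: np.ndarray,
    n_pos: int,
    n_neg: int,
    constraints: CutoffConstraints,
):
    """Per-candidate constraint checks, split by which cutoff they depend on.

    With midpoint candidates never equal to data values, the counts below
    candidate i are cp[i] positives and cn[i] negatives. PPV and PLR
    depend only on the upper cutoff; NPV and NLR only on the lower.
    """
    a = n_pos - cp  # positives above candidate (as upper)
    d = n_neg - cn
    c = cp  # positives below candidate (as lower)
    f = cn
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = np.where(a + d > 0, a / np.maximum(a + d, 1), np.nan)
        npv = np.where(c + f > 0, f / np.maximum(c + f, 1), np.nan)
        plr = np.where(
            d > 0, (a / n_pos) / np.maximum(d / n_neg, 1e-300),
            np.where(a > 0, np.inf, np.nan),
        )
        nlr = np.where(
            f > 0, (c / n_pos) / np.maximum(f / n_neg, 1e-300),
            np.where(c > 0, np.inf, np.nan),
        )
    # an undefined metric counts as a violated constraint
    viol_upper = (~(ppv >= constraints.min_ppv)).astype(int) + (
        ~(plr > constraints.min_plr)
    ).astype(int)
    viol_lower = (~(npv >= constraints.min_npv)).astype(int) + (
        ~(nlr < constraints.max_nlr)
    ).astype(int)
    ppv_tb = np.where(np.isnan(ppv), 0.0, ppv)  # tie-break sum treats NaN as 0
    npv_tb = np.where(np.isnan(npv), 0.0, npv)
    return viol_upper, viol_lower, ppv_tb, npv_tb


def optimize_dual_cutoffs(
    values, labels, constraints: CutoffConstraints | None = None
) -> DualCutoffResult:
    """Exhaustive lossless search for the optimal dual-cutoff pair.

    Candidate thresholds are midpoints of consecutive order statistics
    plus sentinels; all ordered pairs (lower <= upper) are scored. Among
    pairs meeting every constraint the winner minimizes the
    indeterminate-zone fraction, ties broken by (1) smaller upper-lower
    width, (2) larger PPV+NPV (undefined terms count 0), (3) smaller
    lower cutoff, (4) smaller upper cutoff. If no pair is feasible the
    same chain applies after first minimizing the number of violated
    constraints, and the result is flagged infeasible.
    """
    if constraints is None:
        constraints = CutoffConstraints()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("dual-cutoff search requires both disease classes")
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())

    t = candidate_thresholds(values)
    m = t.size
    svals = np.sort(values)
    cum_all = np.searchsorted(svals, t)  # subjects strictly below each candidate
    spos = np.sort(values[labels])
    cp = np.searchsorted(spos, t).astype(float)
    cn = cum_all - cp

    viol_u, viol_l, ppv_tb, npv_tb = _violations_and_keys(
        cp, cn, n_pos, n_neg, constraints
    )

    # pair grid (i = lower index, j = upper index, i <= j)
    viol = viol_l[:, None] + viol_u[None, :]
    inter = (cum_all[None, :] - cum_all[:, None]).astype(float)  # b + e
    width = t[None, :] - t[:, None]
    pvsum = npv_tb[:, None] + ppv_tb[None, :]
    lower_grid = np.broadcast_to(t[:, None], (m, m))
    upper_grid = np.broadcast_to(t[None, :], (m, m))

    invalid = np.arange(m)[:, None] > np.arange(m)[None, :]  # i > j pairs
    big = np.where(invalid, np.inf, 0.0)

    keys = (
        viol + big,
        inter + big,
        width + big,
        -pvsum + big,
        lower_grid + big,
        upper_grid + big,
    )
    order = np.lexsort(tuple(k.ravel() for k in reversed(keys)))
    best = order[0]
    i, j = divmod(int(best), m)
    lower, upper = float(t[i]), float(t[j])
    zones = classify_three_zone(values, lower, upper)
    metrics = classification_metrics(zones, labels)
    n_violated = int(viol[i, j])
    return DualCutoffResult(
        lower=lower,
        upper=upper,
        feasible=n_violated == 0,
        metrics=metrics,
        n_violated=n_violated,
    )


METRIC_NAMES = (
    "ppv", "npv", "sens_pos", "spec_neg", "plr", "nlr",
    "intermediate_plr", "intermediate_fraction",
)


def bootstrap_dual_cutoffs(
    values,
    labels,
    constraints: CutoffConstraints | None = None,
    B: int = 1000,
    seed: int = 0,
    stratified: bool = False,
    aggregate: str = "median",
) -> DualCutoffResult:
    """Bootstrap the dual-cutoff derivation (B subject resamples).

    Per replicate the full constrained search reruns on a resample drawn
    with replacement (unstratified by default; ``stratified`` resamples
    within each disease class). Final cutoffs are the per-threshold
    medians across feasible replicates (``aggregate="original"`` uses
    the original-sample optimum instead); final metrics apply those
    cutoffs to the original sample. 95% CIs are the 2.5/97.5 percentiles
    of each metric across replicates, each replicate's metric evaluated
    at its own cutoffs; undefined replicate values are excluded.
    """
    if B < 1:
        raise ValueError("bootstrap needs B >= 1")
    if aggregate not in ("median", "original"):
        raise ValueError("aggregate must be 'median' or 'original'")
    if constraints is None:
        constraints = CutoffConstraints()
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n = values.size
    rng = np.random.default_rng(int(seed))

    lowers, uppers, feas = [], [], []
    metric_draws: dict[str, list[float]] = {k: [] for k in METRIC_NAMES}
    pos_idx, neg_idx = np.flatnonzero(labels), np.flatnonzero(~labels)
    for _ in range(B):
        if stratified:
            idx = np.concatenate(
                [
                    rng.choice(pos_idx, size=pos_idx.size, replace=True),
                    rng.choice(neg_idx, size=neg_idx.size, replace=True),
                ]
            )
        else:
            idx = rng.integers(0, n, size=n)
            if labels[idx].all() or not labels[idx].any():
                # resample lost a class entirely; redraw counts as infeasible
                feas.append(False)
                lowers.append(np.nan)
                uppers.append(np.nan)
                for k in METRIC_NAMES:
                    metric_draws[k].append(np.nan)
                continue
        rep = optimize_dual_cutoffs(values[idx], labels[idx], constraints)
        feas.append(rep.feasible)
        lowers.append(rep.lower)
        uppers.append(rep.upper)
        md = rep.metrics.as_dict()
        for k in METRIC_NAMES:
            metric_draws[k].append(md[k])

    feas = np.asarray(feas, dtype=bool)
    lowers = np.asarray(lowers, dtype=float)
    uppers = np.asarray(uppers, dtype=float)
    frac_infeasible = float(1.0 - feas.mean())

    point = optimize_dual_cutoffs(values, labels, constraints)
    if aggregate == "median" and feas.any():
        lower = float(np.median(lowers[feas]))
        upper = float(np.median(uppers[feas]))
        if lower > upper:  # medians of dependent thresholds can cross in principle
            lower = upper = float((lower + upper) / 2.0)
    else:
        lower, upper = point.lower, point.upper

    zones = classify_three_zone(values, lower, upper)
    base = classification_metrics(zones, labels)

    ci: dict[str, tuple[float, float]] = {}
    cutoff_ci: dict[str, tuple[float, float]] = {}
    if feas.any():
        for k, draws in metric_draws.items():
            arr = np.asarray(draws, dtype=float)
            ok = np.isfinite(arr)
            if ok.any():
                lo, hi = np.percentile(arr[ok], [2.5, 97.5])
                ci[k] = (float(lo), float(hi))
        for name, arr in (("lower", lowers[feas]), ("upper", uppers[feas])):
            lo, hi = np.percentile(arr, [2.5, 97.5])
            cutoff_ci[name] = (float(lo), float(hi))

    metrics = ClassificationMetrics(
        **{k: getattr(base, k) for k in METRIC_NAMES},
        counts=base.counts,
        undefined=base.undefined,
        ci=ci,
    )
    final_feasible = (
        metrics.ppv >= constraints.min_ppv
        and metrics.npv >= constraints.min_npv
        and metrics.plr > constraints.min_plr
        and metrics.nlr < constraints.max_nlr
    )
    return DualCutoffResult(
        lower=lower,
        upper=upper,
        feasible=bool(final_feasible),
        metrics=metrics,
        n_violated=point.n_violated,
        bootstrap={
            "B": B,
            "seed": int(seed),
            "stratified": stratified,
            "aggregate": aggregate,
            "fraction_infeasible": frac_infeasible,
            "cutoff_ci": cutoff_ci,
            "all_infeasible": bool(~feas.any()),
        },
    )
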