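"""Independent brute-force oracles, deliberately coded without reusing the
package's vectorized search so the two routes can disagree."""

from __future__ import annotations

import numpy as np


def brute_force_dual_cutoffs(values, labels, constraints):
    """Plain-Python exhaustive enumeration over the midpoint candidate grid.

    Implements the documented selection chain directly: feasibility first
    (PPV >= min_ppv, NPV >= min_npv, PLR > min_plr, NLR < max_nlr, with
    undefined metrics counting as violations), then lexicographically
    (n_violated, intermediate count, width, -(ppv+npv with NaN as 0),
    lower, upper). Returns (lower, upper, feasible, metrics_dict).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    u = np.unique(values)
    span = max(1.0, abs(u[0]), abs(u[-1]))
    cands = [u[0] - 0.01 * span]
    for i in range(len(u) - 1):
        cands.append((u[i] + u[i + 1]) / 2.0)
    cands.append(u[-1] + 0.01 * span)

    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    best_key = None
    best = None
    for lo in cands:
        for hi in cands:
            if lo > hi:
                continue
            a = int(((values > hi) & labels).sum())
            b = int(((values >= lo) & (values <= hi) & labels).sum())
            c = int(((values < lo) & labels).sum())
            d = int(((values > hi) & ~labels).sum())
            e = int(((values >= lo) & (values <= hi) & ~labels).sum())
            f = int(((values < lo) & ~labels).sum())
            ppv = a / (a + d) if (a + d) > 0 else float("nan")
            npv = f / (c + f) if (c + f) > 0 else float("nan")
            if d > 0:
                plr = (a / n_pos) / (d / n_neg)
            else:
                plr = float("inf") if a > 0 else float("nan")
            if f > 0:
                nlr = (c / n_pos) / (f / n_neg)
            else:
                nlr = float("inf") if c > 0 else float("nan")
            viol = 0
            if not (ppv >= constraints.min_ppv):
                viol += 1
            if not (npv >= constraints.min_npv):
                viol += 1
            if not (plr > constraints.min_plr):
                viol += 1
            if not (nlr < constraints.max_nlr):
                viol += 1
            pv_sum = (0.0 if np.isnan(ppv) else ppv) + (0.0 if np.isnan(npv) else npv)
            key = (viol, b + e, hi - lo, -pv_sum, lo, hi)
            if best_key is None or key < best_key:
                best_key = key
                best = (
                    lo,
                    hi,
                    viol == 0,
                    {
                        "ppv": ppv,
                        "npv": npv,
                        "plr": plr,
                        "nlr": nlr,
                        "intermediate_fraction": (b + e) / (n_pos + n_neg),
                        "counts": (a, b, c, d, e, f),
                    },
                )
    return best


def trapezoid_auc(scores, labels):
    """AUC by explicit trapezoidal integration of the empirical ROC,
    sweeping unique thresholds by hand."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pts = []
    for t in thresholds:
        called = scores >= t
        tpr = (called & labels).sum() / n_pos
        fpr = (called & ~labels).sum() / n_neg
        pts.append((fpr, tpr))
    pts.append((1.0, 1.0))
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def recursive_partial_corr(x, y, covs):
    """Textbook recursion: partial out one covariate at a time.

    r_{xy.z} = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2)), applied
    successively over covariate columns.
    """
    variables = [np.asarray(x, float), np.asarray(y, float)] + [
        np.asarray(c, float) for c in covs
    ]

    def partial(i, j, given):
        if not given:
            return float(np.corrcoef(variables[i], variables[j])[0, 1])
        k = given[-1]
        rest = given[:-1]
        rij = partial(i, j, rest)
        rik = partial(i, k, rest)
        rjk = partial(j, k, rest)
        return (rij - rik * rjk) / np.sqrt((1 - rik**2) * (1 - rjk**2))

    return partial(0, 1, list(range(2, len(variables))))
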