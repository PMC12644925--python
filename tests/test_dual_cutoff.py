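"""Dual-cutoff framework: zone assignment, three-zone metrics, constrained
search vs a brute-force oracle, bootstrap behavior."""

import numpy as np
import pytest

from plasmapanel import (
    CutoffConstraints,
    ThreeZoneCounts,
    bootstrap_dual_cutoffs,
    classification_metrics,
    classify_three_zone,
    optimize_dual_cutoffs,
)
from plasmapanel.dual_cutoff import metrics_from_counts

from .oracles import brute_force_dual_cutoffs


class TestClassifyThreeZone:
    def test_basic_assignment(self):
        zones = classify_three_zone([1, 2, 3], 1.5, 2.5)
        assert list(zones) == ["negative", "intermediate", "positive"]

    def test_boundaries_are_intermediate(self):
        zones = classify_three_zone([1.5, 2.5], 1.5, 2.5)
        assert list(zones) == ["intermediate", "intermediate"]

    def test_collapsed_zone(self):
        zones = classify_three_zone([1, 2, 3], 2.0, 2.0)
        assert list(zones) == ["negative", "intermediate", "positive"]

    def test_reported_ratio_cutoffs_call_positive(self):
        # a ratio of 0.05 clears the published upper cutoff 0.0374
        zones = classify_three_zone([0.05], 0.0297, 0.0374)
        assert zones[0] == "positive"

    def test_inverted_cutoffs_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            classify_three_zone([1.0], 2.0, 1.0)


class TestClassificationMetrics:
    def test_hand_counted_toy_table(self):
        m = metrics_from_counts(ThreeZoneCounts(a=8, b=1, c=1, d=1, e=1, f=8))
        assert m.ppv == pytest.approx(8 / 9)
        assert m.npv == pytest.approx(8 / 9)
        assert m.plr == pytest.approx(8.0)
        assert m.nlr == pytest.approx(0.125)
        assert m.intermediate_plr == pytest.approx(1.0)
        assert m.intermediate_fraction == pytest.approx(0.10)

    def test_empty_intermediate_reduces_to_binary_identities(self):
        m = metrics_from_counts(ThreeZoneCounts(a=40, b=0, c=10, d=5, e=0, f=45))
        sens, spec = m.sens_pos, m.spec_neg
        assert m.plr == pytest.approx(sens / (1 - spec))
        assert m.nlr == pytest.approx((1 - sens) / spec)

    def test_all_intermediate_undefined_with_reason(self):
        m = metrics_from_counts(ThreeZoneCounts(a=0, b=10, c=0, d=0, e=10, f=0))
        assert np.isnan(m.ppv) and np.isnan(m.npv)
        assert "ppv" in m.undefined and "npv" in m.undefined
        assert m.intermediate_fraction == 1.0

    def test_zone_probabilities_sum_to_one(self, rng):
        for _ in range(20):
            c = ThreeZoneCounts(*(int(v) for v in rng.integers(0, 20, size=6)))
            if c.n_pos == 0 or c.n_neg == 0:
                continue
            m = metrics_from_counts(c)
            assert (c.a + c.b + c.c) / c.n_pos == pytest.approx(1.0)
            assert (
                m.sens_pos + c.b / c.n_pos + c.c / c.n_pos
            ) == pytest.approx(1.0)

    def test_from_zones_and_labels(self):
        values = np.r_[np.full(10, 3.0), np.full(10, 1.0)]
        labels = np.r_[np.ones(10, bool), np.zeros(10, bool)]
        zones = classify_three_zone(values, 2.0, 2.0)
        m = classification_metrics(zones, labels)
        assert m.ppv == 1.0 and m.npv == 1.0
        assert m.intermediate_fraction == 0.0


class TestOptimizeDualCutoffs:
    def test_perfect_separation_collapses_zone(self):
        values = np.r_[np.linspace(0, 1, 20), np.linspace(3, 4, 20)]
        labels = np.r_[np.zeros(20, bool), np.ones(20, bool)]
        res = optimize_dual_cutoffs(values, labels)
        assert res.feasible
        assert res.metrics.intermediate_fraction == 0.0
        assert res.lower == res.upper == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, rng):
        constraints = CutoffConstraints()
        for _ in range(40):
            n = int(rng.integers(8, 41))
            values = np.round(rng.normal(size=n), 2)  # rounding forces ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            got = optimize_dual_cutoffs(values, labels, constraints)
            lo, hi, feas, metrics = brute_force_dual_cutoffs(values, labels, constraints)
            assert got.lower == lo and got.upper == hi
            assert got.feasible == feas
            assert got.metrics.intermediate_fraction == pytest.approx(
                metrics["intermediate_fraction"], abs=0
            )

    def test_vacuous_constraints_empty_zone(self, rng):
        loose = CutoffConstraints(min_ppv=0.0, min_npv=0.0, min_plr=0.0, max_nlr=np.inf)
        for _ in range(10):
            values = rng.normal(size=60)
            labels = rng.random(60) < 0.4
            if labels.all() or not labels.any():
                continue
            res = optimize_dual_cutoffs(values, labels, loose)
            assert res.feasible
            assert res.metrics.intermediate_fraction == 0.0

    def test_tightening_constraint_never_shrinks_zone(self, rng):
        for _ in range(10):
            values = rng.normal(size=100) + rng.random(100)
            labels = values + rng.normal(size=100) > 0.5
            if labels.all() or not labels.any():
                continue
            base = optimize_dual_cutoffs(values, labels, CutoffConstraints())
            tight = optimize_dual_cutoffs(
                values, labels, CutoffConstraints(min_ppv=0.97)
            )
            if base.feasible and tight.feasible:
                assert (
                    tight.metrics.intermediate_fraction
                    >= base.metrics.intermediate_fraction
                )

    def test_exchangeable_labels_infeasible(self, rng):
        # permuted labels at prevalence 0.5: no threshold pair can reach
        # PPV >= 0.9, so the strict default constraints cannot be met
        values = rng.normal(size=600)
        labels = np.r_[np.ones(300, bool), np.zeros(300, bool)]
        rng.shuffle(labels)
        res = optimize_dual_cutoffs(values, labels, CutoffConstraints())
        assert not res.feasible
        assert res.n_violated > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            optimize_dual_cutoffs([1.0, 2.0], [True, True])


@pytest.fixture(scope="module")
def sample():
    rng = np.random.default_rng(5)
    pos = rng.lognormal(0.5, 0.5, size=60)
    neg = rng.lognormal(-0.7, 0.5, size=60)
    return np.r_[pos, neg], np.r_[np.ones(60, bool), np.zeros(60, bool)]


class TestBootstrap:
    def test_seeded_determinism(self, sample):
        values, labels = sample
        a = bootstrap_dual_cutoffs(values, labels, B=50, seed=9)
        b = bootstrap_dual_cutoffs(values, labels, B=50, seed=9)
        assert a.lower == b.lower and a.upper == b.upper
        assert a.metrics.ci == b.metrics.ci

    def test_single_replicate_collapses_ci(self, sample):
        values, labels = sample
        res = bootstrap_dual_cutoffs(values, labels, B=1, seed=3)
        if res.bootstrap["fraction_infeasible"] == 0.0:
            for lo, hi in res.metrics.ci.values():
                assert lo == pytest.approx(hi)

    def test_invalid_b_rejected(self, sample):
        values, labels = sample
        with pytest.raises(ValueError, match="B >= 1"):
            bootstrap_dual_cutoffs(values, labels, B=0)

    def test_original_aggregate_matches_point_estimate(self, sample):
        values, labels = sample
        point = optimize_dual_cutoffs(values, labels)
        res = bootstrap_dual_cutoffs(
            values, labels, B=25, seed=2, aggregate="original"
        )
        assert res.lower == point.lower and res.upper == point.upper

    def test_stratified_preserves_class_sizes(self, sample):
        values, labels = sample
        res = bootstrap_dual_cutoffs(values, labels, B=25, seed=2, stratified=True)
        assert res.bootstrap["stratified"]
        assert res.metrics.ci  # resamples never lose a class

    def test_ci_covers_population_ppv(self):
        """Scaled-down coverage study: the bootstrap PPV interval should
        usually contain the large-sample PPV of the population-optimal
        cutoffs for a known two-lognormal mixture (full-scale version:
        n=238, B=500, 100 outer replications)."""
        from scipy import stats as sps

        mu_p, s_p, mu_n, s_n = 0.5, 0.5, -0.7, 0.5

        # population-optimal cutoffs by numeric search on a fine grid
        grid = np.linspace(0.05, 6.0, 800)
        constraints = CutoffConstraints()
        Sp = sps.lognorm.sf(grid, s_p, scale=np.exp(mu_p))  # P(pos > t)
        Sn = sps.lognorm.sf(grid, s_n, scale=np.exp(mu_n))
        Fp = 1 - Sp
        Fn = 1 - Sn
        best = None
        for i in range(len(grid)):  # lower index
            ok_lo = (Fn[i] / (Fp[i] + Fn[i]) >= constraints.min_npv) and (
                Fp[i] / Fn[i] < constraints.max_nlr
            )
            if not ok_lo:
                continue
            for j in range(i, len(grid)):
                ok_hi = (Sp[j] / (Sp[j] + Sn[j]) >= constraints.min_ppv) and (
                    Sp[j] / Sn[j] > constraints.min_plr
                )
                if ok_hi:
                    inter = (Fp[j] - Fp[i]) + (Fn[j] - Fn[i])
                    if best is None or inter < best[0]:
                        best = (inter, i, j)
                    break  # larger j only widens the zone for this i
        assert best is not None
        _, i, j = best
        pop_ppv = Sp[j] / (Sp[j] + Sn[j])

        rng = np.random.default_rng(17)
        hits = total = 0
        for _ in range(25):
            pos = rng.lognormal(mu_p, s_p, size=75)
            neg = rng.lognormal(mu_n, s_n, size=75)
            values = np.r_[pos, neg]
            labels = np.r_[np.ones(75, bool), np.zeros(75, bool)]
            res = bootstrap_dual_cutoffs(
                values, labels, B=200, seed=int(rng.integers(2**31))
            )
            if "ppv" not in res.metrics.ci:
                continue
            lo, hi = res.metrics.ci["ppv"]
            total += 1
            hits += lo - 1e-12 <= pop_ppv <= hi + 1e-12
        assert total >= 20
        assert hits / total >= 0.8
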