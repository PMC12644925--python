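"""Generator correctness: moment matching, determinism, positivity,
tau-panel structure."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmapanel import (
    default_cohort_config,
    generate_cohort,
    generate_tau_panel,
    lognormal_params_from_moments,
    partial_corr,
)
from plasmapanel.synthetic_cohort import (
    GROUPS,
    TauModel,
    default_tau_model,
)


class TestLognormalMomentMatching:
    def test_point_mass(self):
        assert lognormal_params_from_moments(1.0, 0.0) == (0.0, 0.0)

    def test_cv_one_gives_sigma2_log2(self):
        _, sigma = lognormal_params_from_moments(2.0, 2.0)
        assert sigma**2 == pytest.approx(np.log(2.0), rel=1e-12)

    def test_closed_form_back_substitution(self):
        # analytic lognormal moments must reproduce the requested pair
        mu, sigma = lognormal_params_from_moments(27.64, 6.91)
        assert sigma == pytest.approx(np.sqrt(np.log(1 + (6.91 / 27.64) ** 2)))
        mean = np.exp(mu + sigma**2 / 2)
        sd = mean * np.sqrt(np.exp(sigma**2) - 1)
        assert mean == pytest.approx(27.64, rel=1e-12)
        assert sd == pytest.approx(6.91, rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            lognormal_params_from_moments(0.0, 1.0)
        with pytest.raises(ValueError):
            lognormal_params_from_moments(-3.0, 1.0)

    @given(
        mean=st.floats(0.01, 1e3),
        cv=st.floats(0.0, 3.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_property(self, mean, cv):
        sd = mean * cv
        mu, sigma = lognormal_params_from_moments(mean, sd)
        back_mean = np.exp(mu + sigma**2 / 2)
        back_sd = back_mean * np.sqrt(np.expm1(sigma**2))
        assert back_mean == pytest.approx(mean, rel=1e-9)
        assert back_sd == pytest.approx(sd, rel=1e-6, abs=1e-9)


class TestDefaultConfig:
    def test_group_sizes(self, default_config):
        sizes = tuple(default_config.group_sizes[g] for g in GROUPS)
        assert sizes == (77, 24, 62, 78, 21)

    def test_reported_moments(self, default_config):
        assert default_config.biomarker_moments["AD_dementia"]["ptau217"] == (1.95, 1.11)
        assert default_config.age_moments["Abeta_neg_CU"] == (72.22, 8.03)
        assert default_config.biomarker_moments["Abeta_neg_CU"]["abeta42"] == (27.64, 6.91)

    def test_interpolated_cells_flagged(self, default_config):
        # the amyloid-negative MCI plasma moments are designed stand-ins
        assert ("Abeta_neg_MCI", "ptau217") in default_config.interpolated
        assert ("Abeta_pos_MCI", "abeta42") in default_config.interpolated

    def test_centiloid_sides_of_threshold(self, default_config):
        for g, (mean, _) in default_config.centiloid_moments.items():
            if "pos" in g or g == "AD_dementia":
                assert mean > 20
            else:
                assert mean < 20


class TestGenerateCohort:
    def test_default_size_and_counts(self, cohort, default_config):
        assert len(cohort) == 262
        counts = cohort.df["group"].value_counts()
        for g in GROUPS:
            assert counts[g] == default_config.group_sizes[g]

    def test_empty_config_gives_empty_cohort(self, default_config):
        cfg = dataclasses.replace(
            default_config,
            group_sizes={g: 0 for g in GROUPS},
            n_missing_centiloid=0,
        )
        assert len(generate_cohort(cfg, seed=3)) == 0

    def test_reproducibility_byte_identical(self, default_config):
        a = generate_cohort(default_config, seed=11)
        b = generate_cohort(default_config, seed=11)
        assert a.df.equals(b.df)
        assert a.config_fingerprint == b.config_fingerprint
        c = generate_cohort(default_config, seed=12)
        assert not a.df["ptau217"].equals(c.df["ptau217"])

    def test_positivity_and_ratio_identity(self, big_cohort):
        df = big_cohort.df
        for m in ("ptau217", "abeta42", "gfap"):
            assert (df[m] > 0).all()
        np.testing.assert_allclose(df["ratio"], df["ptau217"] / df["abeta42"], rtol=1e-12)

    def test_age_truncated_at_inclusion_bound(self, big_cohort):
        assert (big_cohort.df["age"] >= 55).all()
        assert (big_cohort.df["education"] >= 0).all()

    def test_unique_subject_ids(self, cohort):
        assert cohort.df["subject_id"].is_unique

    def test_missing_centiloid_count(self, cohort):
        assert cohort.df["centiloid"].isna().sum() == 24
        assert np.isfinite(cohort.df["centiloid"].dropna()).all()

    def test_moment_convergence_subset(self, big_cohort, default_config):
        # spot-check two groups at n=1000/group within 10%; the full 2%
        # check at n=10,000 lives in the acceptance suite
        df = big_cohort.df
        for g in ("Abeta_neg_CU", "AD_dementia"):
            sub = df[df["group"] == g]
            for m, (mean, sd) in default_config.biomarker_moments[g].items():
                assert sub[m].mean() == pytest.approx(mean, rel=0.10)
                assert sub[m].std(ddof=1) == pytest.approx(sd, rel=0.15)


class TestTauPanel:
    def test_default_subset_is_76(self, cohort):
        tau_cols = [c for c in cohort.df.columns if c.startswith("tau_")]
        assert len(tau_cols) == 15
        assert cohort.df[tau_cols].notna().any(axis=1).sum() == 76

    def test_subset_composition_by_stage(self, cohort):
        df = cohort.df
        has_tau = df[[c for c in df.columns if c.startswith("tau_")]].notna().any(axis=1)
        cu = df["group"].isin(("Abeta_neg_CU", "Abeta_pos_CU"))
        assert (has_tau & cu).sum() == 24
        assert (has_tau & ~cu).sum() == 52

    def test_oversized_subset_rejected(self, cohort):
        with pytest.raises(ValueError, match="exceeds cohort"):
            generate_tau_panel(cohort, seed=0, subset_cu=500, subset_impaired=52)

    def test_empty_cohort_rejected(self, default_config):
        cfg = dataclasses.replace(
            default_config, group_sizes={g: 0 for g in GROUPS}, n_missing_centiloid=0
        )
        empty = generate_cohort(cfg, seed=0)
        with pytest.raises(ValueError, match="empty"):
            generate_tau_panel(empty, seed=0)

    def test_zero_loadings_break_association(self, big_cohort):
        model = default_tau_model()
        model = dataclasses.replace(
            model, loadings={r: 0.0 for r in model.regions}
        )
        coh = generate_tau_panel(
            big_cohort, model, seed=5, subset_cu=1000, subset_impaired=2000
        )
        df = coh.df.dropna(subset=["tau_mesial_temporal_left"])
        cov = np.column_stack(
            [df["age"].to_numpy(), (df["sex"] == "F").astype(float).to_numpy()]
        )
        r, _, _ = partial_corr(
            df["ratio"].to_numpy(), df["tau_mesial_temporal_left"].to_numpy(), cov
        )
        assert abs(r) < 0.05

    def test_calibrated_partial_correlation_band(self, big_cohort):
        # the designed world targets ~0.5 for the ratio in mesial temporal
        coh = generate_tau_panel(
            big_cohort, default_tau_model(), seed=5, subset_cu=1500, subset_impaired=2500
        )
        df = coh.df.dropna(subset=["tau_mesial_temporal_composite"])
        cov = np.column_stack(
            [df["age"].to_numpy(), (df["sex"] == "F").astype(float).to_numpy()]
        )
        r, _, _ = partial_corr(
            df["ratio"].to_numpy(),
            df["tau_mesial_temporal_composite"].to_numpy(),
            cov,
        )
        assert 0.4 <= r <= 0.7

    def test_braak_stage_gradient(self, big_cohort):
        # isocortical uptake must be higher in AD dementia than Abeta- CU
        coh = generate_tau_panel(
            big_cohort, default_tau_model(), seed=9, subset_cu=1500, subset_impaired=2500
        )
        df = coh.df.dropna(subset=["tau_frontal_composite"])
        ad = df.loc[df["group"] == "AD_dementia", "tau_frontal_composite"]
        cu = df.loc[df["group"] == "Abeta_neg_CU", "tau_frontal_composite"]
        assert len(ad) >= 500 and len(cu) >= 500
        assert ad.mean() > cu.mean()


class TestTauModelValidation:
    def test_mismatched_regions_rejected(self):
        m = default_tau_model()
        bad = dataclasses.replace(m, loadings={"nowhere": 1.0})
        with pytest.raises(ValueError, match="differ"):
            bad.validate()

    def test_negative_noise_rejected(self):
        m = default_tau_model()
        bad = dataclasses.replace(m, noise_sd={**m.noise_sd, "global": -1.0})
        with pytest.raises(ValueError, match="noise"):
            bad.validate()


def test_config_validation_rejects_bad_probability(default_config):
    cfg = dataclasses.replace(
        default_config,
        sex_female_prob={**default_config.sex_female_prob, "AD_dementia": 1.5},
    )
    with pytest.raises(ValueError, match="outside"):
        cfg.validate()
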