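"""Synthetic cohort generator for plasma biomarker pipeline validation.

Generates subject-level cohorts with the statistical structure the
downstream analyses assume: five diagnostic groups spanning the
Alzheimer's continuum, positively skewed plasma biomarker concentrations
with exact moment matching, a per-subject latent severity inducing the
within-group biomarker/amyloid correlations, and an optional regional
tau-PET panel with a Braak-stage gradient.

Concentrations are drawn from lognormal marginals parameterized so the
natural-scale mean and SD equal the configured targets exactly. The
within-subject dependence comes from two independent standard-normal
latents with per-marker loadings on the log scale (which preserves the
marginals): a disease-severity axis ``z`` driving p-tau217, GFAP and
amyloid-PET burden, and an amyloid-specific axis ``w`` driving Centiloid
and (negatively) Abeta42. The second axis encodes that plasma Abeta42
carries amyloid information not contained in p-tau217 — the property
that makes the p-tau217/Abeta42 ratio the panel's best discriminator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS: tuple[str, ...] = (
    "Abeta_neg_CU",
    "Abeta_pos_CU",
    "Abeta_neg_MCI",
    "Abeta_pos_MCI",
    "AD_dementia",
)
CU_GROUPS: tuple[str, ...] = ("Abeta_neg_CU", "Abeta_pos_CU")
IMPAIRED_GROUPS: tuple[str, ...] = ("Abeta_neg_MCI", "Abeta_pos_MCI", "AD_dementia")
MARKERS: tuple[str, ...] = ("ptau217", "abeta42", "gfap")

#: Centiloid-positivity threshold (CL units) used throughout the pipeline.
CENTILOID_POSITIVE: float = 20.0
#: Global amyloid SUVR corresponding to the Centiloid positivity threshold.
SUVR_AT_THRESHOLD: float = 0.62
#: CL change per unit of global SUVR in the affine SUVR<->CL correspondence.
#: Chosen so the amyloid-negative CU group (SUVR 0.47) sits at CL 0.
CL_PER_SUVR: float = 400.0 / 3.0


def centiloid_to_suvr(cl: float | np.ndarray) -> float | np.ndarray:
    """Affine Centiloid -> global SUVR map anchored at CL 20 <-> SUVR 0.62."""
    return SUVR_AT_THRESHOLD + (np.asarray(cl, dtype=float) - CENTILOID_POSITIVE) / CL_PER_SUVR


@dataclass(frozen=True)
class TauModel:
    """Latent-severity model for regional tau-PET SUVR generation.

    Each region's SUVR is ``baseline(stage) + loading(region) * severity
    + noise(stage)`` where ``severity = group_offset + gamma * z +
    severity_noise_sd * e`` shares the biomarker latent ``z``.
    """

    #: region name -> Braak stage group
    region_stage: Mapping[str, str]
    #: region name -> loading of latent tau severity (SUVR per severity unit)
    loadings: Mapping[str, float]
    #: stage group -> baseline SUVR
    baselines: Mapping[str, float]
    #: stage group -> independent noise SD (SUVR units)
    noise_sd: Mapping[str, float]
    #: diagnostic group -> tau severity offset
    group_offsets: Mapping[str, float]
    #: loading of the biomarker latent z on tau severity
    gamma: float = 0.9
    #: SD of the severity innovation independent of z
    severity_noise_sd: float = 0.45
    #: tau-subset sizes by cognitive stage (CU vs impaired)
    subset_cu: int = 24
    subset_impaired: int = 52

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.region_stage)

    def validate(self) -> None:
        if set(self.region_stage) != set(self.loadings):
            raise ValueError("tau_model: regions in mapping and loadings differ")
        stages = set(self.region_stage.values())
        for name, table in (("baselines", self.baselines), ("noise_sd", self.noise_sd)):
            missing = stages - set(table)
            if missing:
                raise ValueError(f"tau_model: {name} missing stage groups {sorted(missing)}")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("tau_model: noise SDs must be >= 0")
        if self.subset_cu < 0 or self.subset_impaired < 0:
            raise ValueError("tau_model: subset sizes must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator.

    Moments are on the natural (concentration) scale; the generator
    converts them to log-scale lognormal parameters internally.
    """

    group_sizes: Mapping[str, int]
    #: group -> marker -> (mean, sd) on the natural scale
    biomarker_moments: Mapping[str, Mapping[str, tuple[float, float]]]
    age_moments: Mapping[str, tuple[float, float]]
    education_moments: Mapping[str, tuple[float, float]]
    sex_female_prob: Mapping[str, float]
    apoe_carrier_prob: Mapping[str, float]
    centiloid_moments: Mapping[str, tuple[float, float]]
    tau_model: TauModel
    seed: int = 0
    #: log-scale loading of the disease-severity latent z per marker
    biomarker_loadings: Mapping[str, float] = field(
        default_factory=lambda: {"ptau217": 0.6, "abeta42": -0.15, "gfap": 0.5}
    )
    #: log-scale loading of the amyloid-specific latent w per marker
    amyloid_loadings: Mapping[str, float] = field(
        default_factory=lambda: {"abeta42": -0.5}
    )
    #: loading of the severity latent z on centiloid (correlation scale)
    centiloid_loading: float = 0.6
    #: loading of the amyloid latent w on centiloid (correlation scale)
    centiloid_amyloid_loading: float = 0.65
    #: number of subjects whose centiloid is withheld (emulates missing
    #: quantification; the discrimination stage analyzes the remainder)
    n_missing_centiloid: int = 24
    #: (group, marker) pairs whose moments are designed stand-ins rather
    #: than study-reported values
    interpolated: frozenset[tuple[str, str]] = frozenset()

    def validate(self) -> None:
        for g in GROUPS:
            if g not in self.group_sizes:
                raise ValueError(f"group_sizes missing group {g!r}")
            if self.group_sizes[g] < 0:
                raise ValueError(f"group size for {g!r} must be >= 0")
            for m in MARKERS:
                mean, sd = self.biomarker_moments[g][m]
                if mean <= 0:
                    raise ValueError(f"biomarker mean for {g}/{m} must be > 0")
                if sd < 0:
                    raise ValueError(f"biomarker SD for {g}/{m} must be >= 0")
            for table, name in (
                (self.sex_female_prob, "sex_female_prob"),
                (self.apoe_carrier_prob, "apoe_carrier_prob"),
            ):
                p = table[g]
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name}[{g}]={p} outside [0, 1]")
            for table, name in (
                (self.age_moments, "age_moments"),
                (self.education_moments, "education_moments"),
                (self.centiloid_moments, "centiloid_moments"),
            ):
                if table[g][1] < 0:
                    raise ValueError(f"{name}[{g}] SD must be >= 0")
        for m in set(self.biomarker_loadings) | set(self.amyloid_loadings):
            lz = float(self.biomarker_loadings.get(m, 0.0))
            lw = float(self.amyloid_loadings.get(m, 0.0))
            if lz**2 + lw**2 > 1.0:
                raise ValueError(
                    f"loadings for {m} have squared norm > 1 (lz={lz}, lw={lw})"
                )
        if self.centiloid_loading**2 + self.centiloid_amyloid_loading**2 > 1.0:
            raise ValueError("centiloid loadings have squared norm > 1")
        if self.n_missing_centiloid < 0:
            raise ValueError("n_missing_centiloid must be >= 0")
        self.tau_model.validate()

    @property
    def n_total(self) -> int:
        return sum(self.group_sizes[g] for g in GROUPS)

    def fingerprint(self) -> str:
        """Stable hash of the full parameterization including the seed."""

        def _plain(obj):
            if isinstance(obj, Mapping):
                return {str(k): _plain(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, frozenset):
                return sorted(map(list, obj))
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            if isinstance(obj, TauModel):
                return {
                    k: _plain(getattr(obj, k))
                    for k in (
                        "region_stage", "loadings", "baselines", "noise_sd",
                        "group_offsets", "gamma", "severity_noise_sd",
                        "subset_cu", "subset_impaired",
                    )
                }
            return obj

        payload = {
            k: _plain(getattr(self, k))
            for k in (
                "group_sizes", "biomarker_moments", "age_moments",
                "education_moments", "sex_female_prob", "apoe_carrier_prob",
                "centiloid_moments", "tau_model", "seed", "biomarker_loadings",
                "amyloid_loadings", "centiloid_loading",
                "centiloid_amyloid_loading", "n_missing_centiloid", "interpolated",
            )
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's demographics, plasma panel and PET reference."""

    subject_id: str
    group: str
    age: float
    sex: str  # "F" or "M"
    education: float
    apoe_e4_carrier: bool
    ptau217: float  # pg/mL
    abeta42: float  # pg/mL
    ratio: float  # ptau217 / abeta42, dimensionless
    gfap: float
    centiloid: float  # NaN when quantification unavailable
    global_suvr: float
    tau_suvr: Mapping[str, float] | None = None


@dataclass
class Cohort:
    """Ordered subject table plus the fingerprint of its generating config."""

    df: pd.DataFrame
    config_fingerprint: str = "external"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tau_regions(self) -> tuple[str, ...]:
        return tuple(c[len("tau_"):] for c in self.df.columns if c.startswith("tau_"))

    def records(self) -> Iterator[SubjectRecord]:
        regions = self.tau_regions
        for _, row in self.df.iterrows():
            tau = None
            if regions and not all(pd.isna(row[f"tau_{r}"]) for r in regions):
                tau = {r: float(row[f"tau_{r}"]) for r in regions if not pd.isna(row[f"tau_{r}"])}
            yield SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                education=float(row["education"]),
                apoe_e4_carrier=bool(row["apoe_e4_carrier"]),
                ptau217=float(row["ptau217"]),
                abeta42=float(row["abeta42"]),
                ratio=float(row["ratio"]),
                gfap=float(row["gfap"]),
                centiloid=float(row["centiloid"]),
                global_suvr=float(row["global_suvr"]),
                tau_suvr=tau,
            )


def default_braak_regions() -> dict[str, str]:
    """Default 15-region tau-PET panel and its Braak-stage mapping.

    The exact regional variables of the source tau quantification are not
    public; this panel is a designed stand-in following the narrative
    labels (mesial temporal, meta-temporal, temporo-parietal, frontal,
    global composites) with left/right/composite triplets per topography.
    """
    return {
        "mesial_temporal_left": "braak_1_2",
        "mesial_temporal_right": "braak_1_2",
        "mesial_temporal_composite": "braak_1_2",
        "meta_temporal_left": "braak_3_4",
        "meta_temporal_right": "braak_3_4",
        "meta_temporal_composite": "braak_3_4",
        "temporo_parietal_left": "braak_3_4",
        "temporo_parietal_right": "braak_3_4",
        "temporo_parietal_composite": "braak_3_4",
        "frontal_left": "braak_5_6",
        "frontal_right": "braak_5_6",
        "frontal_composite": "braak_5_6",
        "global_left": "global",
        "global_right": "global",
        "global_composite": "global",
    }


def default_tau_model() -> TauModel:
    """Default latent tau-severity model.

    Calibrated by construction (not fitted to any data) so that, after
    age/sex adjustment, the ratio-vs-region partial correlations are
    strong (~0.5) and the Abeta42 row weak/negative, and so that mean
    SUVR in isocortical (Braak V-VI) regions is higher in AD dementia
    than in amyloid-negative CU subjects.
    """
    region_stage = default_braak_regions()
    loadings = {}
    stage_loading = {"braak_1_2": 0.25, "braak_3_4": 0.22, "braak_5_6": 0.16, "global": 0.20}
    for region, stage in region_stage.items():
        # composites aggregate hemispheres: slightly higher loading, less noise
        bump = 1.1 if region.endswith("composite") else 1.0
        loadings[region] = stage_loading[stage] * bump
    return TauModel(
        region_stage=region_stage,
        loadings=loadings,
        baselines={"braak_1_2": 1.30, "braak_3_4": 1.20, "braak_5_6": 1.10, "global": 1.20},
        noise_sd={"braak_1_2": 0.14, "braak_3_4": 0.12, "braak_5_6": 0.10, "global": 0.09},
        group_offsets={
            "Abeta_neg_CU": 0.0,
            "Abeta_pos_CU": 0.7,
            "Abeta_neg_MCI": 0.15,
            "Abeta_pos_MCI": 1.1,
            "AD_dementia": 1.9,
        },
        gamma=0.9,
        severity_noise_sd=0.45,
        subset_cu=24,
        subset_impaired=52,
    )


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Default configuration emulating the reference clinical cohort.

    Group sizes 77/24/62/78/21 across the five diagnostic groups, with
    per-group biomarker, age and education moments equal to the study's
    reported values. Moments the study does not report (amyloid-negative
    MCI plasma markers; Abeta42 in amyloid-positive CU-adjacent gaps) are
    designed stand-ins flagged in ``interpolated``: both amyloid-negative
    groups share the amyloid-negative CU moments, and the missing
    amyloid-positive MCI Abeta42 is placed between the amyloid-positive
    CU and AD dementia values.

    Centiloid moments are the reported global-SUVR moments mapped through
    the affine CL <-> SUVR correspondence anchored at CL 20 <-> SUVR 0.62.
    """
    sizes = dict(zip(GROUPS, (77, 24, 62, 78, 21)))
    ptau = {
        "Abeta_neg_CU": (0.55, 0.36),
        "Abeta_pos_CU": (1.15, 0.46),
        "Abeta_neg_MCI": (0.55, 0.36),  # interpolated: copies Abeta_neg_CU
        "Abeta_pos_MCI": (1.75, 1.69),
        "AD_dementia": (1.95, 1.11),
    }
    abeta = {
        "Abeta_neg_CU": (27.64, 6.91),
        "Abeta_pos_CU": (23.54, 4.63),
        "Abeta_neg_MCI": (27.64, 6.91),  # interpolated
        "Abeta_pos_MCI": (23.00, 5.00),  # interpolated: between Abeta_pos_CU and AD
        "AD_dementia": (22.62, 5.56),
    }
    gfap = {
        "Abeta_neg_CU": (12.30, 7.36),
        "Abeta_pos_CU": (20.67, 10.63),
        "Abeta_neg_MCI": (12.30, 7.36),  # interpolated
        "Abeta_pos_MCI": (21.55, 9.53),
        "AD_dementia": (22.81, 11.04),
    }
    moments = {
        g: {"ptau217": ptau[g], "abeta42": abeta[g], "gfap": gfap[g]} for g in GROUPS
    }
    interpolated = frozenset(
        {
            ("Abeta_neg_MCI", "ptau217"),
            ("Abeta_neg_MCI", "abeta42"),
            ("Abeta_neg_MCI", "gfap"),
            ("Abeta_pos_MCI", "abeta42"),
        }
    )
    age = {
        "Abeta_neg_CU": (72.22, 8.03),
        "Abeta_pos_CU": (77.96, 6.21),
        "Abeta_neg_MCI": (77.79, 7.38),
        "Abeta_pos_MCI": (74.28, 7.64),
        "AD_dementia": (70.24, 10.83),
    }
    education = {
        "Abeta_neg_CU": (11.25, 4.60),
        "Abeta_pos_CU": (9.29, 4.59),
        "Abeta_neg_MCI": (10.69, 5.00),
        "Abeta_pos_MCI": (10.99, 5.32),
        "AD_dementia": (10.10, 4.25),
    }
    sex_female = {
        "Abeta_neg_CU": 0.7273,
        "Abeta_pos_CU": 0.8333,
        "Abeta_neg_MCI": 0.6774,
        "Abeta_pos_MCI": 0.6538,
        "AD_dementia": 0.7619,
    }
    # Carrier rates rise with amyloid status; chosen so the expected total
    # carrier count matches the reported 102 of 262.
    apoe = {
        "Abeta_neg_CU": 0.25,
        "Abeta_pos_CU": 0.50,
        "Abeta_neg_MCI": 0.28,
        "Abeta_pos_MCI": 0.52,
        "AD_dementia": 0.60,
    }
    # Global-SUVR moments mapped through the affine CL correspondence.
    suvr = {
        "Abeta_neg_CU": (0.47, 0.07),
        "Abeta_pos_CU": (0.70, 0.07),
        "Abeta_neg_MCI": (0.47, 0.08),
        "Abeta_pos_MCI": (0.73, 0.09),
        "AD_dementia": (0.77, 0.08),
    }
    centiloid = {
        g: (
            CENTILOID_POSITIVE + (m - SUVR_AT_THRESHOLD) * CL_PER_SUVR,
            s * CL_PER_SUVR,
        )
        for g, (m, s) in suvr.items()
    }
    return CohortConfig(
        group_sizes=sizes,
        biomarker_moments=moments,
        age_moments=age,
        education_moments=education,
        sex_female_prob=sex_female,
        apoe_carrier_prob=apoe,
        centiloid_moments=centiloid,
        tau_model=default_tau_model(),
        seed=seed,
        interpolated=interpolated,
    )


def lognormal_params_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of a lognormal with given natural-scale moments.

    sigma^2 = ln(1 + (sd/mean)^2) and mu = ln(mean) - sigma^2 / 2, so the
    implied lognormal has exactly the requested mean and SD. ``sd = 0``
    degenerates to a point mass at ``mean``.
    """
    if mean <= 0:
        raise ValueError(f"lognormal moment matching requires mean > 0, got {mean}")
    if sd < 0:
        raise ValueError(f"SD must be >= 0, got {sd}")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, size: int
) -> np.ndarray:
    """Rejection-sampled normal draws constrained to [low, inf)."""
    if sd == 0:
        if mean < low:
            raise ValueError(f"degenerate truncated normal: mean {mean} below bound {low}")
        return np.full(size, mean)
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        keep = draw[draw >= low][: size - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Draw a synthetic cohort; identical (config, seed) -> identical cohort.

    Per group: age is normal truncated at 55 (study inclusion bound),
    education truncated at 0, sex and APOE carriage Bernoulli, biomarkers
    lognormal with exact moment matching tied through a per-subject
    latent severity, centiloid normal sharing the same latent. The ratio
    column is always the quotient of its drawn parents. A configurable
    number of subjects have centiloid withheld (NaN).
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(int(seed))

    frames = []
    sid = 0
    for g in GROUPS:
        n = int(config.group_sizes[g])
        if n == 0:
            continue
        z = rng.normal(size=n)  # disease-severity latent
        w = rng.normal(size=n)  # amyloid-specific latent
        age = _truncated_normal(rng, *config.age_moments[g], low=55.0, size=n)
        edu = _truncated_normal(rng, *config.education_moments[g], low=0.0, size=n)
        female = rng.random(n) < config.sex_female_prob[g]
        carrier = rng.random(n) < config.apoe_carrier_prob[g]

        markers = {}
        for m in MARKERS:
            mean, sd = config.biomarker_moments[g][m]
            mu, sigma = lognormal_params_from_moments(mean, sd)
            lz = float(config.biomarker_loadings.get(m, 0.0))
            lw = float(config.amyloid_loadings.get(m, 0.0))
            eps = rng.normal(size=n)
            shock = lz * z + lw * w + np.sqrt(max(0.0, 1.0 - lz**2 - lw**2)) * eps
            markers[m] = np.exp(mu + sigma * shock)

        cl_mean, cl_sd = config.centiloid_moments[g]
        rz, rw = config.centiloid_loading, config.centiloid_amyloid_loading
        cl = cl_mean + cl_sd * (
            rz * z + rw * w + np.sqrt(max(0.0, 1.0 - rz**2 - rw**2)) * rng.normal(size=n)
        )

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"S{sid + i:04d}" for i in range(n)],
                    "group": g,
                    "age": age,
                    "sex": np.where(female, "F", "M"),
                    "education": edu,
                    "apoe_e4_carrier": carrier,
                    "ptau217": markers["ptau217"],
                    "abeta42": markers["abeta42"],
                    "ratio": markers["ptau217"] / markers["abeta42"],
                    "gfap": markers["gfap"],
                    "centiloid": cl,
                    "global_suvr": centiloid_to_suvr(cl),
                    "latent_severity": z,
                }
            )
        )
        sid += n

    if not frames:
        df = pd.DataFrame(
            columns=[
                "subject_id", "group", "age", "sex", "education", "apoe_e4_carrier",
                "ptau217", "abeta42", "ratio", "gfap", "centiloid", "global_suvr",
                "latent_severity",
            ]
        )
        return Cohort(df=df, config_fingerprint=config.fingerprint())

    df = pd.concat(frames, ignore_index=True)
    n_miss = min(config.n_missing_centiloid, len(df))
    if n_miss > 0:
        miss_idx = rng.choice(len(df), size=n_miss, replace=False)
        df.loc[miss_idx, ["centiloid", "global_suvr"]] = np.nan
    return Cohort(df=df, config_fingerprint=config.fingerprint())


def generate_tau_panel(
    cohort: Cohort,
    tau_model: TauModel | None = None,
    seed: int = 0,
    subset_cu: int | None = None,
    subset_impaired: int | None = None,
) -> Cohort:
    """Attach regional tau-PET SUVR values to a stratified subject subset.

    Selects ``subset_cu`` cognitively unimpaired and ``subset_impaired``
    impaired subjects (defaults 24 + 52 = 76, matching the tau-PET
    subsample of the reference study) and fills each selected subject's
    regional SUVRs as ``baseline + loading * severity + stage noise``.
    The tau severity shares the generator's latent z when present, so the
    plasma panel and the tau panel are correlated by construction.
    """
    if tau_model is None:
        tau_model = default_tau_model()
    tau_model.validate()
    if len(cohort) == 0:
        raise ValueError("cannot attach a tau panel to an empty cohort")
    n_cu = tau_model.subset_cu if subset_cu is None else subset_cu
    n_imp = tau_model.subset_impaired if subset_impaired is None else subset_impaired

    df = cohort.df.copy()
    rng = np.random.default_rng(int(seed))
    cu_idx = df.index[df["group"].isin(CU_GROUPS)].to_numpy()
    imp_idx = df.index[df["group"].isin(IMPAIRED_GROUPS)].to_numpy()
    if n_cu > cu_idx.size or n_imp > imp_idx.size:
        raise ValueError(
            f"requested tau subset ({n_cu} CU + {n_imp} impaired) exceeds cohort "
            f"strata sizes ({cu_idx.size} CU, {imp_idx.size} impaired)"
        )
    chosen = np.concatenate(
        [
            rng.choice(cu_idx, size=n_cu, replace=False) if n_cu else np.empty(0, int),
            rng.choice(imp_idx, size=n_imp, replace=False) if n_imp else np.empty(0, int),
        ]
    ).astype(int)
    chosen.sort()

    sub = df.loc[chosen]
    if "latent_severity" in sub.columns:
        z = sub["latent_severity"].to_numpy(dtype=float)
    else:  # externally loaded cohorts carry no latent; use an independent one
        z = rng.normal(size=len(sub))
    offsets = sub["group"].map(dict(tau_model.group_offsets)).to_numpy(dtype=float)
    severity = offsets + tau_model.gamma * z + tau_model.severity_noise_sd * rng.normal(size=len(sub))

    for region in tau_model.regions:
        stage = tau_model.region_stage[region]
        vals = (
            tau_model.baselines[stage]
            + tau_model.loadings[region] * severity
            + tau_model.noise_sd[stage] * rng.normal(size=len(sub))
        )
        df.loc[chosen, f"tau_{region}"] = vals
    return Cohort(df=df, config_fingerprint=cohort.config_fingerprint)
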