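# Methods

This note documents the statistical procedures `plasmapanel` implements,
the synthetic world its generator states, the numerical conventions, and
the limits of what a green test establishes.

## The analysis battery

### Group comparisons

Continuous demographics are compared with classical one-way ANOVA;
the implementation computes the between/within decomposition from group
summary statistics, so raw-data and published-summary entry points are
algebraically identical (F = [Σnᵢ(mᵢ−m̄)²/(k−1)] / [Σ(nᵢ−1)sᵢ²/(N−k)]).
Proportions use Pearson χ² without continuity correction (the default
large-sample practice; all expected counts in the intended tables are
well above 5). `counts_from_percentages` reconstructs integer counts
from printed percentages and errors when the implied count is more than
0.51 percentage points from an integer — a guard against mistyped
tables.

Biomarker group differences use ANCOVA (`value ~ group + age + sex`,
female = 1) with a partial F-test (full vs covariate-only model) for
the group factor; adjusted means are fitted values at the covariate
means. Post hoc pairwise contrasts come from the *same* adjusted model,
with Bonferroni correction (p·k(k−1)/2, capped at 1). Constant covariate
columns are dropped rather than raising: a constant duplicates the
intercept and carries no adjustment information, and this convention
makes the ANCOVA degrade gracefully to plain ANOVA.

*APOE* ε4 comparisons use the Welch (unequal-variance) t-test with
Satterthwaite df, two-tailed. Welch rather than pooled: biomarker
variances differ grossly between carriers and non-carriers (e.g. SDs
1.58 vs 0.76 pg/mL for p-tau217), and the Welch statistic reproduces
the published worked example. Significance is two-tailed α = 0.05
throughout.

### Discrimination

AUC is the Mann–Whitney pair-counting statistic with the ½-tie
convention, computed via midranks; it equals trapezoidal integration of
the empirical ROC exactly (tested to 1e−12). Confidence intervals are
DeLong structural-component intervals (normal approximation, clipped to
[0, 1]); DeLong was chosen over a bootstrap because it is the standard
for empirical AUCs, deterministic, and needs no resampling seed.

Covariate-augmented scores are fitted probabilities from a
maximum-likelihood logistic model `amyloid ~ biomarker + APOEε4`
(statsmodels Logit; tol 1e−8, 100 iterations). On separation or
non-convergence the function warns and falls back to the raw biomarker
ranking, explicitly flagged — unstable coefficients would otherwise
produce an arbitrary ROC. Note that raw-marker AUCs are
direction-sensitive: Aβ42 *decreases* with amyloid, so its raw AUC is
below 0.5; the logistic route handles direction automatically.

The amyloid reference is Centiloid > 20. Discrimination runs on the
subset with a valid Centiloid value (no imputation); the default
synthetic cohort withholds Centiloid for 24 of 262 subjects to emulate
incomplete PET quantification, leaving the 238-subject analysis set.
Cognitive-stage subgroups are CU = {Aβ− CU, Aβ+ CU} and impaired =
{Aβ− MCI, Aβ+ MCI, AD dementia}.

### Dual-cutoff classification

Subjects above the upper cutoff are called positive, below the lower
negative, and in the closed interval between them *intermediate* (the
boundary-inclusive convention is the conservative choice). From the
zone occupancies (a, b, c) of the diseased and (d, e, f) of the
non-diseased:

    PPV  = a/(a+d)          NPV  = f/(c+f)
    PLR  = (a/n₊)/(d/n₋)    NLR  = (c/n₊)/(f/n₋)
    iPLR = (b/n₊)/(e/n₋)    zone fraction = (b+e)/N

Likelihood ratios use full-class denominators, so the three zone
probabilities sum to one within each class — the only convention under
which an intermediate-zone likelihood ratio is coherent. PPV/NPV
condition on the call actually made (intermediate subjects appear in
neither), the natural reading of predictive values in a three-zone
test. Zero denominators yield an explicit undefined-with-reason value
(or +∞ for a likelihood ratio with positive numerator), never a silent
drop.

**Search.** Candidate thresholds are midpoints between consecutive
order statistics plus one sentinel beyond each extreme; any other
threshold induces the same partition of the observed sample, so the
grid is lossless. All ordered pairs are scored (vectorized via the
observation that PPV/PLR depend only on the upper cutoff and NPV/NLR
only on the lower). Among pairs satisfying every constraint
(PPV ≥ 0.90 and NPV ≥ 0.90 non-strict; PLR > 5.0 and NLR < 0.1 strict,
exactly as the targets are conventionally printed), the winner
minimizes the intermediate fraction, ties broken by (1) smaller
upper−lower width, (2) larger PPV+NPV (undefined terms count 0),
(3) smaller lower, (4) smaller upper. If nothing is feasible the same
chain applies after minimizing the number of violated constraints, and
the result is flagged. An undefined metric counts as a violated
constraint. The implementation is verified bit-for-bit against a
plain-Python exhaustive enumeration on 200 random small instances.

**Bootstrap.** B = 1000 subject resamples (with replacement,
unstratified by default; a stratified option exists). Each replicate
re-runs the full search; final cutoffs are per-threshold medians across
*feasible* replicates, and final metrics apply those cutoffs to the
original sample. 95% CIs are 2.5/97.5 percentiles of each metric across
replicates, each evaluated at its own replicate's cutoffs; percentile
rather than BCa intervals are the simplest defensible choice. The
fraction of infeasible replicates is recorded; if every replicate is
infeasible the CIs are undefined and the result flagged. Because median
aggregation can land on a pair that misses a constraint on the full
sample by a hair, the point-estimate-on-original-sample alternative is
available (`aggregate="original"`), and feasibility of the returned
pair is always re-checked on the full sample.

### Tau-PET partial correlations

Partial correlation is residual-based: both variables are regressed on
an intercept + age + sex by OLS and the Pearson correlation of the
residual vectors is tested with t = r√(df/(1−r²)), df = n − 2 − k. This
agrees with the textbook recursive partial-correlation formula to 1e−8
(tested) and with `pingouin.partial_corr`. Regions are grouped and
ordered Braak I–II → III–IV → V–VI → global. Cells carry raw-p tiers
(* < 0.05, ** < 0.01, *** < 0.001) with **no** multiplicity correction
across the 4 × 15 grid — matching how such heatmaps are conventionally
annotated — so individual asterisks in a 60-cell grid must be read
accordingly. Subjects missing a region are dropped cell-wise with the
per-cell n reported.

The shipped 15-region panel (mesial-temporal, meta-temporal,
temporo-parietal, frontal and global left/right/composite triplets) is
a **designed stand-in**: the exact regional variables of the upstream
tau quantification are not public, so the mapping ships as an editable
configuration (`BraakMapping.from_frame`) and all tests use the
default.

## The synthetic world

The generator states a specific world; its defaults are fixed, not
tuning knobs.

**Groups.** Five diagnostic groups, sizes 77/24/62/78/21. Per-group
age, education, sex and biomarker moments equal the reference study's
reported values. Moments that study does not report are flagged
`interpolated` in the config: both amyloid-negative groups share the
Aβ− CU plasma moments (both are amyloid-negative, and the Aβ− MCI
plasma values are unreported), and the unreported Aβ+ MCI Aβ42 is set
to 23.00 ± 5.00, between the Aβ+ CU and AD dementia values.

**Marginals.** Concentrations are lognormal with exact moment matching:
σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2. Lognormal because
concentrations are positive and right-skewed, and because the Aβ+ MCI
p-tau217 group has SD ≈ mean — impossible for a normal without negative
draws. Age is normal truncated at 55 (the study's inclusion bound) by
rejection sampling; education truncated at 0.

**Dependence.** Two independent standard-normal latents per subject:
a disease-severity axis z and an amyloid-specific axis w. Log-scale
loadings: p-tau217 0.6·z, GFAP 0.5·z, Aβ42 −0.15·z − 0.5·w; Centiloid
0.6·z + 0.65·w (on the correlation scale; residual variance fills to
1, so marginals are preserved exactly). Two axes rather than one
because plasma Aβ42's diagnostic value lies in amyloid information
*not* contained in p-tau217: with a single shared latent, Aβ42 is
redundant and the ratio's designed advantages (higher AUC, smaller
indeterminate zone) hold only marginally. The two-latent world encodes
the mechanism and makes those orderings robust (verified across 100
seeds). Centiloid moments are the reported global-SUVR moments mapped
through the affine correspondence CL = 20 + (SUVR − 0.62)·(400/3),
anchored so SUVR 0.62 ↔ CL 20 and the Aβ− CU group mean sits at CL 0;
`global_suvr` is the inverse image of the drawn Centiloid.

**APOE.** Carrier probabilities rise with amyloid status
(0.25/0.50/0.28/0.52/0.60), chosen so the expected carrier count is
~102 of 262 as reported; carrier-level biomarker shifts then emerge
from group composition alone rather than an extra within-group effect.

**Tau panel.** A stratified 24 CU + 52 impaired = 76-subject subset
receives 15 regional SUVRs: baseline(stage) + loading(region)·severity
+ stage noise, with severity = group offset + 0.9·z + 0.45·noise.
Offsets (0, 0.7, 0.15, 1.1, 1.9 across the five groups) and loadings
(0.25/0.22/0.16/0.20 per stage, ×1.1 for composites) were calibrated
by construction — not fitted to any data — so that age/sex-adjusted
ratio-vs-region partial correlations sit near 0.5 at large n, the Aβ42
row is weak/negative, and Braak V–VI uptake is higher in AD dementia
than Aβ− CU.

**What the generator does not emulate.** No longitudinal trajectories,
no assay noise structure or batch effects, no missingness mechanisms
beyond the withheld-Centiloid count, no secondary pathologies, and a
class overlap wider than a well-characterized clinical cohort's —
synthetic indeterminate zones (~30–40%) are therefore much larger than
published clinical ones (~8–13%). Green tests establish that the
*procedures* are correct and that *designed orderings* hold; they do
not reproduce any clinical effect size.

## Numerical conventions

- All RNG flows through `numpy.random.default_rng`; the pipeline
  derives independent per-stage substreams from one master seed via
  `SeedSequence.spawn`, so adding a stage never perturbs earlier ones.
  Identical (config, seed) reruns are byte-identical.
- ANOVA F = 0 (zero between- and within-group variance) reports p = 1;
  identical degenerate t-test strata report t = 0, p = 1.
- DeLong variance uses midrank placements; sample variance with
  ddof = 1.
- Logistic separation is detected by statsmodels' warnings, failed
  convergence, or |coefficient| > 1e6.
- Output tables are TSV, floats at 4 significant digits, p-values at 3;
  sex is encoded F/M in CSV and mapped to 1/0 internally; missing
  values are empty fields.

## Known limitations

- The dual-cutoff search is O(m²) in the number of unique values —
  instant at cohort scale (m ≈ 240), but not intended for n ≫ 10⁴.
- Bootstrap median aggregation of cutoffs can return a pair that is
  marginally infeasible on the full sample (flagged, never hidden).
- The PPV/NPV denominators exclude intermediate-zone subjects by
  construction; analyses that require intent-to-diagnose denominators
  need the zone fraction alongside.
- No paired AUC-difference test, cost-weighted cutoff selection,
  prevalence adjustment, or external-validation split.
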