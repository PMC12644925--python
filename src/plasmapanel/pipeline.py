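"""End-to-end orchestration: simulate/load -> describe -> ROC -> cutoffs -> tau.

All randomness flows from one configured seed through independent
per-stage substreams (adding a stage never perturbs earlier stages), and
reruns with the same config are byte-identical. Output tables are
tab-separated with one header row; floats are printed at 4 significant
digits, p-values at 3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from plasmapanel import __version__ as _version
from plasmapanel.synthetic_cohort import (
    GROUPS,
    MARKERS,
    CENTILOID_POSITIVE,
    Cohort,
    CohortConfig,
    default_cohort_config,
    generate_cohort,
    generate_tau_panel,
)
from plasmapanel.group_comparisons import (
    ancova_adjusted,
    bonferroni_posthoc,
    descriptive_table,
    ttest_by_carrier,
)
from plasmapanel.discrimination import roc_summary_table
from plasmapanel.dual_cutoff import CutoffConstraints, bootstrap_dual_cutoffs
from plasmapanel.tau_correlation import braak_heatmap, default_braak_mapping

REQUIRED_COLUMNS = (
    "subject_id", "group", "age", "sex", "education", "apoe_e4_carrier",
    "ptau217", "abeta42", "ratio", "gfap", "centiloid", "global_suvr",
)
DEFAULT_MARKERS = ("ptau217", "abeta42", "ratio", "gfap")
CUTOFF_MARKERS = ("ptau217", "ratio")


@dataclass
class RunConfig:
    """Parameterization of one pipeline run."""

    mode: str = "simulate"  # "simulate" | "load"
    cohort_path: str | None = None
    seed: int = 0
    markers: tuple[str, ...] = DEFAULT_MARKERS
    cl_threshold: float = CENTILOID_POSITIVE
    constraints: CutoffConstraints = field(default_factory=CutoffConstraints)
    bootstrap_B: int = 1000
    strata: tuple[str, ...] = ("all", "CU", "impaired")
    outdir: str = "plasmapanel_out"
    with_tau: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")
        if self.mode == "load" and not self.cohort_path:
            raise ValueError("load mode requires cohort_path")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")
        if not np.isfinite(self.cl_threshold):
            raise ValueError("cl_threshold must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "constraints" in raw:
            raw["constraints"] = CutoffConstraints(**raw["constraints"])
        for key in ("markers", "strata"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunManifest:
    """Record of everything a run produced."""

    config: dict
    seed: int
    version: str
    outputs: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        payload = asdict(self)
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _fmt(x) -> str:
    if isinstance(x, float):
        if np.isnan(x):
            return ""
        return f"{x:.4g}"
    return str(x)


def write_tsv(df: pd.DataFrame, path: Path, p_cols: tuple[str, ...] = ()) -> None:
    out = df.copy()
    for c in out.columns:
        if c in p_cols:
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else f"{float(v):.3g}")
        elif out[c].dtype.kind == "f":
            out[c] = out[c].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def write_cohort_csv(cohort: Cohort, path: str | Path) -> None:
    """One row per subject; tau regions as tau_-prefixed columns; missing
    values are empty fields."""
    df = cohort.df.drop(columns=["latent_severity"], errors="ignore").copy()
    df["apoe_e4_carrier"] = df["apoe_e4_carrier"].astype(int)
    df.to_csv(path, index=False)


def write_config_sidecar(config: CohortConfig, path: str | Path) -> None:
    """YAML sidecar with every generator parameter and the seed."""

    def plain(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {k: plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
        if isinstance(obj, dict):
            return {str(k): plain(v) for k, v in obj.items()}
        if isinstance(obj, frozenset):
            return sorted([list(x) for x in obj])
        if isinstance(obj, (list, tuple)):
            return [plain(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    Path(path).write_text(yaml.safe_dump(plain(config), sort_keys=True))


def read_cohort_csv(path: str | Path) -> Cohort:
    violations = validate_cohort_csv(path)
    if violations:
        raise ValueError(
            "cohort CSV failed validation:\n" + "\n".join(f"  - {v}" for v in violations)
        )
    df = pd.read_csv(path)
    df["apoe_e4_carrier"] = df["apoe_e4_carrier"].astype(bool)
    return Cohort(df=df, config_fingerprint="external")


def validate_cohort_csv(path: str | Path) -> list[str]:
    """Schema check; returns a list of violations (empty on success)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable / not CSV
        raise OSError(f"cannot read {path}: {exc}") from exc
    problems: list[str] = []
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        return problems
    if len(df) == 0:
        return ["cohort has 0 rows"]
    dup = df["subject_id"][df["subject_id"].duplicated()]
    for sid in dup.unique():
        problems.append(f"duplicated subject_id {sid!r}")
    bad_groups = ~df["group"].isin(GROUPS)
    for i in df.index[bad_groups]:
        problems.append(f"row {i}: group {df.loc[i, 'group']!r} not in {GROUPS}")
    bad_sex = ~df["sex"].isin(["F", "M"])
    for i in df.index[bad_sex]:
        problems.append(f"row {i}: sex {df.loc[i, 'sex']!r} must be 'F' or 'M'")
    for col in ("age", "education", "ptau217", "abeta42", "gfap", "centiloid"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            problems.append(f"column {col!r} is not numeric")
    for col in MARKERS:
        if pd.api.types.is_numeric_dtype(df[col]):
            for i in df.index[df[col] <= 0]:
                problems.append(f"row {i}: column {col!r} must be > 0, got {df.loc[i, col]}")
    return problems


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Independent per-stage substreams derived from the single run seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(child.generate_state(1)[0] % 2**31) for child in ss.spawn(n)]


def run_pipeline(
    config: RunConfig,
    cohort_config: CohortConfig | None = None,
) -> RunManifest:
    """Execute all stages in order and write publication-shaped tables.

    Stage order: cohort (simulate or load), descriptives and adjusted
    group tests, ROC per marker/stratum, dual cutoffs for p-tau217 and
    the ratio, Braak-stratified tau partial correlations (skipped with a
    warning when the cohort has no tau columns).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={**{k: getattr(config, k) for k in (
            "mode", "cohort_path", "seed", "markers", "cl_threshold",
            "bootstrap_B", "strata", "outdir", "with_tau")},
            "constraints": asdict(config.constraints)},
        seed=config.seed,
        version=_version,
    )
    gen_seed, tau_seed, boot_seed, _spare = _stage_seeds(config.seed)

    def emit(name: str) -> Path:
        manifest.outputs.append(name)
        return outdir / name

    # stage 1: cohort
    if config.mode == "simulate":
        if cohort_config is None:
            cohort_config = default_cohort_config(seed=config.seed)
        cohort = generate_cohort(cohort_config, seed=gen_seed)
        if config.with_tau:
            cohort = generate_tau_panel(cohort, cohort_config.tau_model, seed=tau_seed)
        write_cohort_csv(cohort, emit("cohort.csv"))
        write_config_sidecar(cohort_config, emit("cohort_config.yaml"))
    else:
        cohort = read_cohort_csv(config.cohort_path)

    df = cohort.df

    # stage 2: descriptives + adjusted group comparisons + APOE t-tests
    write_tsv(descriptive_table(df), emit("descriptives.tsv"), p_cols=("p_value",))
    covariates = pd.DataFrame(
        {"age": df["age"].to_numpy(float), "sex_female": (df["sex"] == "F").astype(float)}
    )
    group_tests: dict = {}
    posthoc_frames = []
    for marker in config.markers:
        res, adj_means = ancova_adjusted(df[marker], df["group"], covariates)
        tt = ttest_by_carrier(df[marker].to_numpy(float), df["apoe_e4_carrier"].to_numpy(bool))
        group_tests[marker] = {
            "ancova_F": res.statistic,
            "ancova_df": res.df,
            "ancova_p": res.p_value,
            "adjusted_means": adj_means,
            "apoe_t": tt.statistic,
            "apoe_df": tt.df[0],
            "apoe_p": tt.p_value,
            "apoe_direction": tt.effect_direction,
        }
        ph = bonferroni_posthoc(df[marker], df["group"], covariates).to_frame()
        ph.insert(0, "marker", marker)
        posthoc_frames.append(ph)
    (outdir / "group_tests.json").write_text(
        json.dumps(group_tests, indent=2, default=float) + "\n"
    )
    manifest.outputs.append("group_tests.json")
    write_tsv(
        pd.concat(posthoc_frames, ignore_index=True),
        emit("posthoc_bonferroni.tsv"),
        p_cols=("p_raw", "p_bonferroni"),
    )

    # stage 3: ROC per marker and stratum, with and without APOE
    try:
        roc_df = roc_summary_table(
            cohort, markers=config.markers, strata=config.strata,
            cl_threshold=config.cl_threshold,
        )
        write_tsv(roc_df, emit("roc_summary.tsv"))
    except ValueError as exc:
        manifest.warnings.append(f"roc stage failed: {exc}")

    # stage 4: dual cutoffs for p-tau217 and the ratio
    sub = df.dropna(subset=["centiloid"])
    labels = sub["centiloid"].to_numpy(float) > config.cl_threshold
    rows = []
    for marker in CUTOFF_MARKERS:
        if marker not in config.markers:
            continue
        res = bootstrap_dual_cutoffs(
            sub[marker].to_numpy(float), labels,
            constraints=config.constraints, B=config.bootstrap_B, seed=boot_seed,
        )
        if not res.feasible:
            detail = (
                "median-aggregated bootstrap cutoffs miss a constraint on the "
                "full sample" if res.n_violated == 0 else
                f"{res.n_violated} constraint(s) unmet even at the optimum"
            )
            manifest.warnings.append(
                f"dual-cutoff constraints not all met for {marker} ({detail})"
            )
        m = res.metrics
        ci = dict(m.ci)
        cut_ci = res.bootstrap["cutoff_ci"] if res.bootstrap else {}

        def ci_str(name: str, scale: float = 1.0) -> str:
            if name not in ci:
                return ""
            lo, hi = ci[name]
            return f"{scale * lo:.4g}-{scale * hi:.4g}"

        rows.append(
            {
                "marker": marker,
                "N": int(len(sub)),
                "lower_cutoff": res.lower,
                "upper_cutoff": res.upper,
                "lower_ci": "-".join(f"{v:.4g}" for v in cut_ci.get("lower", ()))
                or "",
                "upper_ci": "-".join(f"{v:.4g}" for v in cut_ci.get("upper", ()))
                or "",
                "intermediate_pct": 100.0 * m.intermediate_fraction,
                "ppv_pct": 100.0 * m.ppv,
                "npv_pct": 100.0 * m.npv,
                "plr": m.plr,
                "nlr": m.nlr,
                "plr_ci": ci_str("plr"),
                "nlr_ci": ci_str("nlr"),
                "ppv_ci": ci_str("ppv", 100.0),
                "npv_ci": ci_str("npv", 100.0),
                "intermediate_plr": m.intermediate_plr,
                "intermediate_plr_ci": ci_str("intermediate_plr"),
                "feasible": res.feasible,
            }
        )
    if rows:
        write_tsv(pd.DataFrame(rows), emit("dual_cutoffs.tsv"))

    # stage 5: Braak-stratified tau partial correlations
    has_tau = any(c.startswith("tau_") for c in df.columns)
    if has_tau:
        mapping = default_braak_mapping()
        for stratum in config.strata:
            try:
                mat = braak_heatmap(cohort, mapping, stratum=stratum)
            except ValueError as exc:
                manifest.warnings.append(f"tau stage skipped for {stratum}: {exc}")
                continue
            write_tsv(
                mat.to_long(), emit(f"tau_partial_corr_{stratum}.tsv"),
                p_cols=("p_value",),
            )
    else:
        manifest.warnings.append("no tau_ columns present; tau stage skipped")

    manifest.outputs.append("manifest.json")
    manifest.write(outdir / "manifest.json")
    return manifest
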