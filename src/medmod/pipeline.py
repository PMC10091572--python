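"""End-to-end orchestration: ingest, descriptives, mediation, moderated
mediation, sensitivity re-run, and table emission.

``run_full_analysis`` reproduces the full analysis sequence of the study
design this package targets: descriptive statistics and bivariate
correlations; a Mann-Whitney sex comparison of each outcome; simple
mediation (X -> M -> each outcome) with bias-corrected percentile bootstrap
intervals; first- and second-stage moderated mediation for each moderator x
outcome combination with simple-effect tables; and, when the sensitivity
flag is set, the same analyses with the covariates dropped.

Reproducibility: one master seed in the config is forked into per-stage
substreams with ``numpy.random.SeedSequence`` keyed by a fixed stage order,
so adding or removing one analysis never shifts another stage's draws, and
re-running the same config reproduces the bundle exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import mediation as med
from . import moderated as mod
from . import stats_core as stc
from . import synthetic as syn

__all__ = [
    "AnalysisConfig",
    "ReportBundle",
    "PipelineError",
    "validate_input",
    "run_full_analysis",
    "SCALE_RANGES",
]

# Admissible total-score ranges used by the ingestion filter (min, max).
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "ct": (25.0, 125.0),
    "se": (10.0, 40.0),
    "cr": (6.0, 42.0),
    "es": (4.0, 28.0),
    "phq9": (0.0, 27.0),
    "gad7": (0.0, 21.0),
    "age": (18.0, 120.0),
    "sex": (0.0, 1.0),
}

_STAGE_ORDER = (
    "simulate",
    "mediation",
    "moderated",
    "sensitivity_mediation",
    "sensitivity_moderated",
)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return float(obj)


class PipelineError(RuntimeError):
    """A named stage of the pipeline failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Everything needed to re-run the analysis deterministically."""

    x: str = "ct"
    m: str = "se"
    outcomes: tuple[str, ...] = ("phq9", "gad7")
    moderators: tuple[str, ...] = ("cr", "es")
    covariates: tuple[str, ...] = ("age", "sex")
    input_csv: str | None = None  # None -> simulate from the study moments
    moment_spec: syn.MomentSpec | None = None  # custom synthetic spec (programmatic)
    demographics: syn.DemographicSpec | None = None
    n: int = syn.STUDY_N
    n_boot: int = 5000
    method: str = "bias_corrected"
    level: float = 0.95
    seed: int = 0
    sensitivity: bool = True
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.outcomes = tuple(self.outcomes)
        self.moderators = tuple(self.moderators)
        self.covariates = tuple(self.covariates)
        if self.n_boot < 1:
            raise ValueError("n_boot must be at least 1")
        if not self.outcomes:
            raise ValueError("at least one outcome is required")

    @classmethod
    def from_json(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=_json_default)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage substream of the master seed (< 2**31)."""
        order = _STAGE_ORDER.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(_STAGE_ORDER))[order]
        return int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))


def validate_input(
    path: str | Path,
    mapping: Mapping[str, str],
    ranges: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Read a participant CSV, enforce completeness and admissible ranges.

    ``mapping`` maps analysis roles/variable names to CSV column names.
    Rows missing any mapped field are dropped (complete-case filter) and the
    drop is recorded in ``df.attrs['ingestion']``; more than 50% dropped is
    a hard error.  Values outside the admissible range for a known variable
    are an error naming the row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    missing_cols = [c for c in mapping.values() if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"mapped columns not present in {path.name}: {missing_cols}")
    df = raw[[mapping[k] for k in mapping]].copy()
    df.columns = list(mapping)
    complete = df.notna().all(axis=1)
    dropped = raw.index[~complete].tolist()
    if len(dropped) > 0.5 * len(df):
        raise ValueError(
            f"{len(dropped)} of {len(df)} rows incomplete (>50%); refusing to proceed"
        )
    df = df[complete].reset_index(drop=True)
    ranges = dict(SCALE_RANGES if ranges is None else ranges)
    for var in df.columns:
        if var not in ranges:
            continue
        lo, hi = ranges[var]
        bad = (df[var] < lo) | (df[var] > hi)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"value {df.loc[row, var]:g} in column {mapping[var]!r} (row {row}) "
                f"outside admissible range [{lo:g}, {hi:g}] for {var!r}"
            )
    df.attrs["ingestion"] = {
        "source": str(path),
        "n_read": int(len(raw)),
        "n_kept": int(len(df)),
        "dropped_rows": dropped,
    }
    return df


@dataclass
class ReportBundle:
    """All output tables of one full analysis run, plus a run log."""

    config: AnalysisConfig
    data: pd.DataFrame
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    correlation_pvalues: pd.DataFrame
    sex_tests: pd.DataFrame
    mediation: dict[str, med.MediationResult]
    stage_fits: dict[tuple[str, str], mod.StageModels]
    conditional: dict[tuple[str, str], mod.ConditionalEffectTable]
    sensitivity_mediation: dict[str, med.MediationResult] = field(default_factory=dict)
    sensitivity_conditional: dict[tuple[str, str], mod.ConditionalEffectTable] = field(
        default_factory=dict
    )
    run_log: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        out: dict[str, pd.DataFrame] = {
            "descriptives": self.descriptives.reset_index(),
            "correlations": self.correlations.reset_index(),
            "correlation_pvalues": self.correlation_pvalues.reset_index(),
            "sex_tests": self.sex_tests,
        }
        for y, res in self.mediation.items():
            out[f"mediation_{y}"] = res.to_frame()
        for (w, y), fits in self.stage_fits.items():
            out[f"stage_first_{w}_{y}"] = fits.first.to_frame()
            out[f"stage_second_{w}_{y}"] = fits.second.to_frame()
        for (w, y), table in self.conditional.items():
            out[f"conditional_{w}_{y}"] = table.to_frame()
        for y, res in self.sensitivity_mediation.items():
            out[f"sensitivity_mediation_{y}"] = res.to_frame()
        for (w, y), table in self.sensitivity_conditional.items():
            out[f"sensitivity_conditional_{w}_{y}"] = table.to_frame()
        return out

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables().items():
            table.to_csv(out / f"{name}.csv", index=False)
        bundle = {
            "config": dataclasses.asdict(self.config),
            "run_log": self.run_log,
            "tables": {
                name: json.loads(t.to_json(orient="records"))
                for name, t in self.tables().items()
            },
        }
        with open(out / "bundle.json", "w") as fh:
            json.dump(bundle, fh, indent=2, default=_json_default)
        return out


def _load_data(config: AnalysisConfig) -> pd.DataFrame:
    needed = [config.x, config.m, *config.outcomes, *config.moderators, *config.covariates]
    if config.input_csv is not None:
        return validate_input(config.input_csv, {v: v for v in dict.fromkeys(needed)})
    spec = config.moment_spec if config.moment_spec is not None else syn.study_moment_spec()
    if config.demographics is not None:
        demo = config.demographics
    elif config.moment_spec is None:
        demo = syn.study_demographics(config.n)
    else:
        demo = None
    return syn.generate_scale_level(
        spec, config.n, seed=config.stage_seed("simulate"), demographics=demo
    )


def run_full_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis sequence for one configuration.

    Any stage failure is re-raised as :class:`PipelineError` naming the
    stage; no partial output directory is written on failure (tables are
    only emitted by ``ReportBundle.write`` after the run completes).
    """
    import time

    t0 = time.perf_counter()
    stage = "ingest"
    try:
        data = _load_data(config)
        analysis_vars = [
            config.x,
            config.m,
            *config.outcomes,
            *config.moderators,
            *config.covariates,
        ]
        stage = "describe"
        desc = stc.describe(data, analysis_vars)
        stage = "correlations"
        corr = stc.pearson_matrix(data, analysis_vars)
        stage = "sex_comparison"
        sex_rows = []
        if "sex" in data.columns:
            for yvar in config.outcomes:
                res = stc.mann_whitney_u(data[yvar], data["sex"])
                sex_rows.append(
                    {"outcome": yvar, "U": res.u, "p": res.p, "n1": res.n1, "n2": res.n2}
                )
        sex_tests = pd.DataFrame(sex_rows)

        stage = "mediation"
        med_seed = config.stage_seed("mediation")
        mediation_results = {
            yvar: med.bootstrap_effects(
                data,
                config.x,
                config.m,
                yvar,
                covariates=config.covariates,
                n_boot=config.n_boot,
                method=config.method,
                level=config.level,
                seed=med_seed + i,
            )
            for i, yvar in enumerate(config.outcomes)
        }

        stage = "moderated"
        mod_seed = config.stage_seed("moderated")
        stage_fits: dict[tuple[str, str], mod.StageModels] = {}
        conditional: dict[tuple[str, str], mod.ConditionalEffectTable] = {}
        for j, w in enumerate(config.moderators):
            for i, yvar in enumerate(config.outcomes):
                stage_fits[(w, yvar)] = mod.fit_stage_models(
                    data, config.x, config.m, yvar, w, config.covariates
                )
                conditional[(w, yvar)] = mod.bootstrap_conditional(
                    data,
                    config.x,
                    config.m,
                    yvar,
                    w,
                    covariates=config.covariates,
                    n_boot=config.n_boot,
                    method=config.method,
                    level=config.level,
                    seed=mod_seed + 10 * j + i,
                )

        sens_med: dict[str, med.MediationResult] = {}
        sens_cond: dict[tuple[str, str], mod.ConditionalEffectTable] = {}
        if config.sensitivity and config.covariates:
            stage = "sensitivity"
            smed_seed = config.stage_seed("sensitivity_mediation")
            smod_seed = config.stage_seed("sensitivity_moderated")
            for i, yvar in enumerate(config.outcomes):
                sens_med[yvar] = med.bootstrap_effects(
                    data,
                    config.x,
                    config.m,
                    yvar,
                    covariates=(),
                    n_boot=config.n_boot,
                    method=config.method,
                    level=config.level,
                    seed=smed_seed + i,
                )
            for j, w in enumerate(config.moderators):
                for i, yvar in enumerate(config.outcomes):
                    sens_cond[(w, yvar)] = mod.bootstrap_conditional(
                        data,
                        config.x,
                        config.m,
                        yvar,
                        w,
                        covariates=(),
                        n_boot=config.n_boot,
                        method=config.method,
                        level=config.level,
                        seed=smod_seed + 10 * j + i,
                    )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    import medmod

    bundle = ReportBundle(
        config=config,
        data=data,
        descriptives=desc,
        correlations=corr.r,
        correlation_pvalues=corr.p,
        sex_tests=sex_tests,
        mediation=mediation_results,
        stage_fits=stage_fits,
        conditional=conditional,
        sensitivity_mediation=sens_med,
        sensitivity_conditional=sens_cond,
        run_log={
            "seed": config.seed,
            "n": int(len(data)),
            "n_boot": config.n_boot,
            "method": config.method,
            "pd_repair_max_change": float(data.attrs.get("pd_repair_max_change", 0.0)),
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "medmod_version": medmod.__version__,
            "numpy_version": np.__version__,
        },
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle
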