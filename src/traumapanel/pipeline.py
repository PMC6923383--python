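"""Configuration-driven orchestration: synthesize/load -> preprocess ->
select -> evaluate -> report.

A :class:`PipelineConfig` (YAML-serializable) names the input (CSV paths
per time point, or a synthetic spec), the preprocessing threshold, the
selection and evaluation settings, and which analyses to run: one per
time point and/or one on the integrated multi-time-point matrix (the
latter with a stricter selection threshold).  Clinical severity scores
are excluded from the selection design matrix and instead appended to
the selected panel during evaluation, yielding the "markers", "markers
+NISS", "markers+PS14" model family.

Child seeds are derived per stage from the master seed, so the same
configuration and seed reproduce the run bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cohort import CohortTable
from .evaluation import EvalConfig, EvalResult, evaluate_panel, univariate_panel
from .preprocess import (
    DEFAULT_MISSING_THRESHOLD,
    PreprocessReport,
    integrate_timepoints,
    preprocess_table,
    retain_complete_patients,
)
from .selection import SelectionConfig, SelectionResult, stability_select
from .synthetic import SyntheticSpec, generate_cohort, inject_missingness

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline", "export_report"]

log = logging.getLogger(__name__)

MODES = ("per-timepoint", "integrated")


@dataclass
class PipelineConfig:
    """All tunables of a full run."""

    #: CSV paths, one per time point (alternative to ``synthetic``)
    input_csvs: list[str] | None = None
    #: synthetic cohort spec (alternative to ``input_csvs``)
    synthetic: SyntheticSpec | None = None
    #: apply missingness injection to the synthetic cohort before preprocessing
    synthetic_missingness: bool = True
    clinical_scores: list[str] = field(default_factory=lambda: ["NISS", "PS14", "ISS"])
    missing_threshold: float = DEFAULT_MISSING_THRESHOLD
    modes: tuple[str, ...] = MODES
    include_clinical_in_selection: bool = False
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.input_csvs is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_csvs or synthetic must be set")
        for m in self.modes:
            if m not in MODES:
                raise ValueError(f"unknown mode {m!r}; choose from {MODES}")
        if not self.modes:
            raise ValueError("modes must be nonempty")
        self.selection.validate()
        self.evaluation.validate()

    # -- YAML round-trip --------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "input_csvs": self.input_csvs,
            "synthetic": self.synthetic.to_dict() if self.synthetic else None,
            "synthetic_missingness": self.synthetic_missingness,
            "clinical_scores": list(self.clinical_scores),
            "missing_threshold": self.missing_threshold,
            "modes": list(self.modes),
            "include_clinical_in_selection": self.include_clinical_in_selection,
            "selection": dataclasses.asdict(self.selection),
            "evaluation": dataclasses.asdict(self.evaluation),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        d["selection"]["alphas"] = list(self.selection.alphas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic"):
            d["synthetic"] = SyntheticSpec.from_dict(d["synthetic"])
        if d.get("selection"):
            sel = dict(d["selection"])
            if "alphas" in sel:
                sel["alphas"] = tuple(sel["alphas"])
            d["selection"] = SelectionConfig(**sel)
        if d.get("evaluation"):
            d["evaluation"] = EvalConfig(**d["evaluation"])
        if d.get("modes"):
            d["modes"] = tuple(d["modes"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunManifest:
    """Reproducibility record written with every run."""

    config: dict
    version: str
    master_seed: int
    stage_seeds: dict[str, int]
    n_patients: int = 0
    dropped_features: dict[str, dict[str, float]] = field(default_factory=dict)
    selection_redraws: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


@dataclass
class AnalysisResult:
    """Selection + evaluation outputs of one analysis (one Fig.-style run)."""

    name: str
    selection: SelectionResult
    panel: list[str]
    multivariate: EvalResult | None
    univariate: list[EvalResult]
    dumbbell: "object"  # pd.DataFrame
    augmented: dict[str, EvalResult]
    notes: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    analyses: dict[str, AnalysisResult]
    manifest: RunManifest
    preprocess_reports: dict[str, PreprocessReport]


def _stage_seeds(master: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    children = ss.spawn(len(names))
    return {
        n: int(np.random.default_rng(c).integers(2**31 - 1))
        for n, c in zip(names, children)
    }


def _load_tables(config: PipelineConfig) -> list[CohortTable]:
    if config.synthetic is not None:
        spec = config.synthetic
        cohort, _ = generate_cohort(spec)
        if config.synthetic_missingness:
            cohort = inject_missingness(cohort, spec)
        return cohort.split_by_timepoint()
    tables = [
        CohortTable.from_csv(p, clinical_columns=config.clinical_scores)
        for p in config.input_csvs
    ]
    return tables


def _run_analysis(
    name: str,
    table: CohortTable,
    config: PipelineConfig,
    sel_config: SelectionConfig,
    eval_seed: int,
    manifest: RunManifest,
) -> AnalysisResult:
    roles = None if config.include_clinical_in_selection else "immune"
    design = table.subset_features(table.features(role=roles)) if roles else table
    selection = stability_select(design, sel_config)
    manifest.selection_redraws[name] = selection.n_redraws
    panel = selection.combined
    ev = dataclasses.replace(config.evaluation, seed=eval_seed)
    notes: list[str] = []
    clinical_present = [c for c in config.clinical_scores if c in table.data.columns]
    if not panel:
        notes.append("no features selected")
        manifest.warnings.append(f"{name}: no features selected")
        import pandas as pd

        return AnalysisResult(name, selection, [], None, [], pd.DataFrame(), {}, notes)
    uni, multi, dumbbell = univariate_panel(table, panel, ev)
    augmented = {}
    for c in clinical_present:
        augmented[f"+{c}"] = evaluate_panel(table, panel + [c], ev)
    return AnalysisResult(name, selection, panel, multi, uni, dumbbell, augmented, notes)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured analyses end to end."""
    config.validate()
    tables = _load_tables(config)
    tables = retain_complete_patients(tables)
    tps = [t.feature_meta["timepoint"].mode().iat[0] for t in tables]
    stage_names = ["preprocess"] + [f"select:{tp}" for tp in tps] + [
        "select:integrated"
    ] + [f"eval:{tp}" for tp in tps] + ["eval:integrated"]
    seeds = _stage_seeds(config.seed, stage_names)
    manifest = RunManifest(
        config=config.to_dict(),
        version=__version__,
        master_seed=config.seed,
        stage_seeds=seeds,
        n_patients=tables[0].n_patients,
    )

    processed = []
    reports: dict[str, PreprocessReport] = {}
    for tp, t in zip(tps, tables):
        pt, rep = preprocess_table(t, config.missing_threshold)
        processed.append(pt)
        reports[tp] = rep
        manifest.dropped_features[tp] = rep.dropped_features

    analyses: dict[str, AnalysisResult] = {}
    if "per-timepoint" in config.modes:
        for tp, pt in zip(tps, processed):
            sel = dataclasses.replace(config.selection, seed=seeds[f"select:{tp}"])
            analyses[tp] = _run_analysis(tp, pt, config, sel, seeds[f"eval:{tp}"], manifest)
    if "integrated" in config.modes:
        integrated, rep = integrate_timepoints(processed)
        reports["integrated"] = rep
        sel = dataclasses.replace(
            config.selection.stringent(), seed=seeds["select:integrated"]
        )
        analyses["integrated"] = _run_analysis(
            "integrated", integrated, config, sel, seeds["eval:integrated"], manifest
        )
    return PipelineResult(analyses=analyses, manifest=manifest, preprocess_reports=reports)


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def export_report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write JSON/CSV outputs and a human-readable summary.

    Deterministic given the result (no timestamps); returns the paths
    written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    manifest_path = out / "manifest.json"
    result.manifest.to_json(manifest_path)
    written.append(manifest_path)
    for name, rep in result.preprocess_reports.items():
        p = out / f"preprocess_{name}.json"
        rep.to_json(p)
        written.append(p)

    lines = [f"traumapanel {result.manifest.version} run summary", ""]
    for name, ana in result.analyses.items():
        adir = out / name
        adir.mkdir(exist_ok=True)
        ana.selection.to_json(adir / "selection.json")
        written.append(adir / "selection.json")
        written += ana.selection.write_csvs(adir)
        lines.append(f"[{name}]")
        lines.append(f"  selected panel: {ana.panel if ana.panel else '(no features selected)'}")
        if ana.multivariate is None:
            lines.append("  no features selected; evaluation skipped")
            lines.append("")
            continue
        ana.dumbbell.to_csv(adir / "dumbbell.csv", index=False)
        written.append(adir / "dumbbell.csv")
        models = {"markers": ana.multivariate, **ana.augmented}
        for label, res in models.items():
            safe = label.replace("+", "plus_")
            p = adir / f"eval_{safe}.json"
            res.to_json(p)
            written.append(p)
            lines.append(
                f"  {label}: AUC {_fmt(res.real_mean)} ± {_fmt(res.real_sd)} "
                f"(permuted {_fmt(res.permuted_mean)} ± {_fmt(res.permuted_sd)}; "
                f"95% CI [{_fmt(res.ci[0])}, {_fmt(res.ci[1])}]; "
                f"p = {res.p_value:.4g}, corrected {res.p_value_corrected:.4g})"
            )
        for f, res in zip(ana.panel, ana.univariate):
            lines.append(f"    univariate {f}: AUC {_fmt(res.real_mean)}")
        lines.append("")
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n")
    written.append(summary)
    return written
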