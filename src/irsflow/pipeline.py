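"""End-to-end orchestration: simulate or ingest a cohort, compute the IRS
indices, run the prediction layer, and write a deterministic report.

Stages run in a fixed order — cytometry summaries, index table, cohort
dose–response and ANOVA, correlations with RTOG grade, Gaussian-centile
classifiers, ROC per index — and the same config plus seed reproduces the
output files byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cytometry import GateSpec, GatedStatistic, gated_statistic, read_events
from .irs_indices import (
    IRSIndexTable,
    build_gm_grids,
    compute_index_table,
    cohort_mean_dose_response,
)
from .prediction import (
    HIGH,
    ClassifierReport,
    ROCResult,
    anova_across_doses,
    bootstrap_auc_ci,
    classify_and_score,
    gaussian_threshold,
    pearson,
    roc_analysis,
)
from .synthetic_cohort import CohortConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    reporting_dose: float = 2.0
    k_values: tuple[int, ...] = (1, 2)
    positive_grade: int = 2
    bootstrap_reps: int = 2000
    seed: int = 0


@dataclass
class RunConfig:
    mode: str = "full"  # simulate | analyze | full
    events_dir: str | None = None
    metadata_path: str | None = None
    out_dir: str = "irs_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gate: GateSpec = field(default_factory=lambda: GateSpec(
        mode="rectangle", scatter1_range=(200.0, 2000.0), scatter2_range=(0.0, 2000.0),
        min_events_after_gate=100,
    ))
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze", "full"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        cohort = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("cohort", {}).items()
        })
        gate_raw = raw.pop("gate", None)
        gate = GateSpec(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in gate_raw.items()
        }) if gate_raw is not None else cls.__dataclass_fields__["gate"].default_factory()
        analysis_raw = raw.pop("analysis", {})
        analysis = AnalysisConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in analysis_raw.items()
        })
        return cls(cohort=cohort, gate=gate, analysis=analysis, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the scientific configuration (cohort, gate, analysis);
        input/output paths are deliberately excluded so relocating a run
        does not change its provenance."""
        payload = {
            "cohort": dataclasses.asdict(self.cohort),
            "gate": dataclasses.asdict(self.gate),
            "analysis": dataclasses.asdict(self.analysis),
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Every number the pipeline reports, traceable to its stage."""

    n_patients: int
    grade_counts: dict[int, int]
    pct_grade_ge2: float
    pct_grade_0_1: float
    index_table: IRSIndexTable
    cohort_gm_means: dict[float, float]
    cohort_slope: float
    cohort_r2: float
    anova_f: float
    anova_p: float
    correlations: list = field(default_factory=list)
    classifiers: list = field(default_factory=list)
    rocs: dict[str, ROCResult] = field(default_factory=dict)
    auc_cis: dict[str, tuple[float, float]] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def grade_prevalence(grades) -> tuple[float, float]:
    """Percent of patients at RTOG grade >= 2 and at grades 0-1."""
    grades = np.asarray(list(grades), dtype=int)
    if grades.size == 0:
        raise ValueError("empty grade vector")
    if ((grades < 0) | (grades > 4)).any():
        raise ValueError("RTOG grades must lie in 0-4")
    pct_ge2 = 100.0 * float((grades >= 2).mean())
    return pct_ge2, 100.0 - pct_ge2


def simulate(config: RunConfig, out_dir: str | Path | None = None):
    """Stage 1: draw the synthetic cohort and write its event files."""
    patients, samples = simulate_cohort(config.cohort)
    target = Path(out_dir or config.out_dir) / "events"
    write_cohort(patients, samples, target)
    logger.info("simulated %d patients, %d samples -> %s", len(patients), len(samples), target)
    return patients, samples, target


def load_events(events_dir: str | Path, metadata_path: str | Path | None = None):
    """Read every event table in a directory plus the cohort metadata."""
    events_dir = Path(events_dir)
    paths = sorted(p for p in events_dir.iterdir() if p.suffix in (".csv", ".fcs")
                   and p.name not in ("cohort.csv", "latent_truth.csv"))
    if not paths:
        raise ValueError(f"no event files found in {events_dir}")
    samples = [read_events(p) for p in paths]
    meta_path = Path(metadata_path) if metadata_path else events_dir / "cohort.csv"
    metadata = pd.read_csv(meta_path)
    return samples, metadata


#: index columns analysed against grade, with their sensitive direction
_INDEX_DIRECTIONS = {"dsb": HIGH, "residual": HIGH, "slope": HIGH}


def analyze(samples, metadata: pd.DataFrame, config: RunConfig) -> StudyReport:
    """Stages 2-5: gated statistics through classifiers and ROC."""
    stats: list[GatedStatistic] = []
    for sample in samples:
        try:
            stats.append(gated_statistic(sample, config.gate))
        except ValueError as exc:
            raise ValueError(f"cytometry stage failed for {sample.source}: {exc}") from exc

    grids = build_gm_grids(stats)
    table = compute_index_table(grids, metadata, reporting_dose=config.analysis.reporting_dose)
    means, cohort_slope, cohort_r2, _ = cohort_mean_dose_response(grids)
    t_ind = grids[0].induction_time
    anova_f, anova_p = anova_across_doses(
        {d: np.array([g.value(d, t_ind) for g in grids]) for d in grids[0].doses}
    )

    frame = table.frame
    grades = frame["rtog_grade"].to_numpy(dtype=float)
    counts = {g: int((grades == g).sum()) for g in range(5)}
    pct_ge2, pct_01 = grade_prevalence(grades.astype(int))

    dose_cols = [c for c in metadata.columns if c.startswith("dose_")]
    surface_mean = metadata.set_index("patient_id").loc[frame["patient_id"], dose_cols].mean(axis=1)

    report = StudyReport(
        n_patients=len(frame),
        grade_counts=counts,
        pct_grade_ge2=pct_ge2,
        pct_grade_0_1=pct_01,
        index_table=table,
        cohort_gm_means=means,
        cohort_slope=cohort_slope,
        cohort_r2=cohort_r2,
        anova_f=anova_f,
        anova_p=anova_p,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.analysis.seed,
            "irsflow_version": __version__,
        },
    )

    index_cols = [c for c in frame.columns if c.startswith(("dsb_", "residual", "slope")) and c != "slope_r2"]
    for col in index_cols:
        values = frame[col].to_numpy(dtype=float)
        try:
            report.correlations.append(pearson(values, grades, index_name=col))
        except ValueError as exc:
            report.skipped.append(f"pearson[{col}]: {exc}")
    try:
        report.correlations.append(
            pearson(surface_mean.to_numpy(dtype=float), grades, index_name="surface_dose")
        )
    except ValueError as exc:
        report.skipped.append(f"pearson[surface_dose]: {exc}")

    for col in index_cols:
        values = frame[col].to_numpy(dtype=float)
        for k in config.analysis.k_values:
            try:
                rule = gaussian_threshold(values, k=k, direction=HIGH, index_name=col)
                report.classifiers.append(
                    classify_and_score(values, grades, rule, positive_grade=config.analysis.positive_grade)
                )
            except ValueError as exc:
                report.skipped.append(f"classifier[{col}, k={k}]: {exc}")
        try:
            labels = grades >= config.analysis.positive_grade
            roc = roc_analysis(values, labels, direction=HIGH)
            report.rocs[col] = roc
            if config.analysis.bootstrap_reps > 0:
                report.auc_cis[col] = bootstrap_auc_ci(
                    values, labels, n_boot=config.analysis.bootstrap_reps,
                    seed=config.analysis.seed,
                )
        except ValueError as exc:
            report.skipped.append(f"roc[{col}]: {exc}")
    for note in report.skipped:
        logger.warning("stage skipped: %s", note)
    return report


def run(config: RunConfig) -> StudyReport | None:
    """Execute the configured mode; analyze/full modes return the report."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.mode == "simulate":
        simulate(config, out_dir)
        return None
    if config.mode == "analyze":
        samples, metadata = load_events(config.events_dir, config.metadata_path)
    else:  # full
        patients, samples, events_dir = simulate(config, out_dir)
        samples, metadata = load_events(events_dir)
    report = analyze(samples, metadata, config)
    write_report(report, out_dir)
    return report


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Serialize CSV/JSON artifacts plus a human-readable summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.index_table.to_csv(out_dir / "indices.csv")

    pd.DataFrame(
        [
            {"index": c.index_name, "r": c.r, "p_value": c.p_value, "n_used": c.n_used}
            for c in report.correlations
        ]
    ).to_csv(out_dir / "correlations.csv", index=False, float_format="%.10g")

    payload = {
        "classifiers": [c.as_dict() for c in report.classifiers],
        "roc": {
            name: {
                "auc": roc.auc,
                "optimal_cutoff": roc.optimal_cutoff,
                "optimal_method": roc.optimal_method,
                "auc_ci95": list(report.auc_cis.get(name, ())) or None,
            }
            for name, roc in report.rocs.items()
        },
        "skipped": report.skipped,
        "provenance": report.provenance,
    }
    (out_dir / "classifier.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    for name, roc in report.rocs.items():
        pd.DataFrame(roc.points, columns=["fpr", "tpr"]).to_csv(
            out_dir / f"roc_{name}.csv", index=False, float_format="%.10g"
        )

    lines = [
        "# IRS study report",
        "",
        f"Patients: {report.n_patients}",
        f"RTOG grade counts: {report.grade_counts}",
        f"Grade >= 2: {report.pct_grade_ge2:.1f}%  |  grades 0-1: {report.pct_grade_0_1:.1f}%",
        "",
        f"Cohort mean dose-response slope: {report.cohort_slope:.3f} dGM/Gy (R^2 = {report.cohort_r2:.4f})",
        f"One-way ANOVA across doses: F = {report.anova_f:.3f}, p = {report.anova_p:.3g}",
        "",
        "## Correlations with RTOG grade",
    ]
    for c in report.correlations:
        lines.append(f"- {c.index_name}: r = {c.r:.3f} (p = {c.p_value:.3g}, n = {c.n_used})")
    lines += ["", "## Threshold classifiers (positive: grade >= 2)"]
    for cl in report.classifiers:
        lines.append(
            f"- {cl.rule.index_name} @ mean+{cl.rule.k}SD = {cl.rule.cutoff:.3f}: "
            f"sens {_fmt(cl.sensitivity)} spec {_fmt(cl.specificity)} acc {_fmt(cl.accuracy)} "
            f"ppv {_fmt(cl.ppv)} npv {_fmt(cl.npv)}"
        )
    lines += ["", "## ROC"]
    for name, roc in report.rocs.items():
        ci = report.auc_cis.get(name)
        ci_txt = f", 95% CI [{ci[0]:.3f}, {ci[1]:.3f}]" if ci else ""
        lines.append(f"- {name}: AUC = {roc.auc:.3f}{ci_txt}, Youden cutoff = {roc.optimal_cutoff:.3f}")
    if report.skipped:
        lines += ["", "## Skipped stages"] + [f"- {s}" for s in report.skipped]
    lines += ["", f"Provenance: {report.provenance}", ""]
    (out_dir / "report.md").write_text("\n".join(lines))


def _fmt(value: float | None) -> str:
    return "undefined" if value is None else f"{value:.1f}%"
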