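"""End-to-end orchestration: trials -> metrics -> reliability report.

A run reads trials from a manifest (or synthesizes a cohort), computes the
twelve sway variables per trial, assembles per-condition test-retest tables
and a cohort summary with Romberg quotients, and writes everything plus a
config copy and a log under one output directory.  Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .copio import CoPTrial, TrialSet, read_manifest, write_trialset
from .timedomain import (
    SwayMetrics,
    positional_variability,
    path_lengths,
    mean_velocity,
)
from .swayarea import fao_area, fit_pca_ellipse, DEFAULT_M_MAX, DEFAULT_N_INTERVALS
from .fractal import fd_all, SHORT_WINDOW_S, LONG_WINDOW_S
from .reliability import reliability_table, romberg_table
from .synthetic import SyntheticConfig, generate_cohort

__all__ = [
    "RunConfig",
    "VARIABLE_LABELS",
    "METRIC_COLUMNS",
    "compute_metrics",
    "metrics_table",
    "render_condition_table",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

#: conventional display names, used as row labels in rendered tables
VARIABLE_LABELS: dict[str, str] = {
    "sd_ml_cm": "Medio-lateral variability (cm)",
    "sd_ap_cm": "Antero-posterior variability (cm)",
    "path_ml_cm": "Medio-lateral path length (cm)",
    "path_ap_cm": "Antero-posterior path length (cm)",
    "path_total_cm": "Total path length (cm)",
    "mean_velocity_cm_s": "Mean velocity (cm/s)",
    "area_fao_cm2": "Sway area FAO (cm2)",
    "area_pca_cm2": "Sway area PCA (cm2)",
    "fd_ml_short": "Fractal dimension ML short interval",
    "fd_ml_long": "Fractal dimension ML long interval",
    "fd_ap_short": "Fractal dimension AP short interval",
    "fd_ap_long": "Fractal dimension AP long interval",
}

METRIC_COLUMNS: list[str] = list(VARIABLE_LABELS)

CONDITION_TITLES = {
    "FO": "Standing on a firm surface with eyes open",
    "FC": "Standing on a firm surface with eyes closed",
    "CO": "Standing on a compliant surface with eyes open",
    "CC": "Standing on a compliant surface with eyes closed",
}


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; serialized next to its outputs."""

    manifest: str | None = None
    synthetic: SyntheticConfig | None = None
    out_dir: str = "stabilometry_run"
    m_max: int = DEFAULT_M_MAX
    n_intervals: int = DEFAULT_N_INTERVALS
    short_window_s: tuple[float, float] = SHORT_WINDOW_S
    long_window_s: tuple[float, float] = LONG_WINDOW_S
    rq_pair: tuple[str, str] = ("FO", "FC")
    rq_variables: tuple[str, ...] = ("path_total_cm", "area_pca_cm2")
    alpha: float = 0.05
    seed: int = 0
    write_trials: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.manifest is None and self.synthetic is None:
            self.synthetic = SyntheticConfig(seed=self.seed)
        if self.manifest is not None and self.synthetic is not None:
            raise ValueError("give either a manifest or a synthetic config, not both")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def compute_metrics(
    trial: CoPTrial,
    m_max: int = DEFAULT_M_MAX,
    n_intervals: int = DEFAULT_N_INTERVALS,
    short_window_s: tuple[float, float] = SHORT_WINDOW_S,
    long_window_s: tuple[float, float] = LONG_WINDOW_S,
) -> SwayMetrics:
    """All twelve sway variables of one trial."""
    sd_ml, sd_ap = positional_variability(trial)
    p_ml, p_ap, p_tot = path_lengths(trial)
    vel = mean_velocity(trial)
    area_fao, _ = fao_area(trial, n_intervals=n_intervals, m_max=m_max)
    area_pca = fit_pca_ellipse(trial).area_cm2
    fits = fd_all(trial, short_window_s=short_window_s, long_window_s=long_window_s)
    return SwayMetrics(
        sd_ml_cm=sd_ml,
        sd_ap_cm=sd_ap,
        path_ml_cm=p_ml,
        path_ap_cm=p_ap,
        path_total_cm=p_tot,
        mean_velocity_cm_s=vel,
        area_fao_cm2=area_fao,
        area_pca_cm2=area_pca,
        fd_ml_short=fits[("ML", "short")].fd,
        fd_ml_long=fits[("ML", "long")].fd,
        fd_ap_short=fits[("AP", "short")].fd,
        fd_ap_long=fits[("AP", "long")].fd,
    )


def metrics_table(trialset: TrialSet, **metric_kwargs) -> pd.DataFrame:
    """Wide per-trial metrics table: metadata plus the twelve variables.

    A trial whose metrics cannot be computed (e.g. a degenerate outline) is
    skipped with a logged error; the run continues.
    """
    rows = []
    for trial in trialset:
        try:
            m = compute_metrics(trial, **metric_kwargs)
        except Exception as exc:  # noqa: BLE001 — per-trial isolation is the contract
            logger.error(
                "metrics failed for subject=%s condition=%s session=%d: %s",
                trial.subject_id,
                trial.condition.value,
                trial.session,
                exc,
            )
            continue
        rows.append(
            {
                "subject_id": trial.subject_id,
                "group": trial.group.value,
                "condition": trial.condition.value,
                "session": trial.session,
                **m.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def _fmt(x: float, nd: int = 2) -> str:
    return f"{x:.{nd}f}"


def render_condition_table(rel: pd.DataFrame, condition: str) -> str:
    """Markdown test-retest table for one condition, in the classic layout.

    Rows are variable x group; columns show per-session mean +/- SD (SE),
    ICC and its 95 % CI, and the standard error of measurement.  Values are
    rounded to 2 decimals for display (CSV outputs keep full precision).
    """
    sub = rel[rel["condition"] == condition]
    lines = [
        f"### {CONDITION_TITLES.get(condition, condition)}",
        "",
        "| Variable | Group | 1st measurement mean ± SD (SE) | "
        "2nd measurement mean ± SD (SE) | ICC | 95% CI | SEM |",
        "|---|---|---|---|---|---|---|",
    ]
    for var in METRIC_COLUMNS:
        block = sub[sub["variable"] == var]
        for _, row in block.iterrows():
            lines.append(
                f"| {VARIABLE_LABELS.get(var, var)} | {row['group'].capitalize()} | "
                f"{_fmt(row['mean1'])} ± {_fmt(row['sd1'])} ({_fmt(row['se1'])}) | "
                f"{_fmt(row['mean2'])} ± {_fmt(row['sd2'])} ({_fmt(row['se2'])}) | "
                f"{_fmt(row['icc'])} | {_fmt(row['ci_low'])}–{_fmt(row['ci_high'])} | "
                f"{_fmt(row['sem_measurement'])} |"
            )
    lines.append("")
    return "\n".join(lines)


def _cohort_summary(metrics: pd.DataFrame, rq: pd.DataFrame) -> str:
    lines = ["## Cohort summary", ""]
    counts = (
        metrics.groupby("group")["subject_id"].nunique().to_dict()
        if not metrics.empty
        else {}
    )
    for group, n in counts.items():
        lines.append(f"- {group}: {n} subjects")
    lines.append("")
    if not rq.empty:
        lines.append("| Romberg quotient | Group | mean ± SD |")
        lines.append("|---|---|---|")
        for _, row in rq.iterrows():
            label = VARIABLE_LABELS.get(row["variable"], row["variable"])
            lines.append(
                f"| RQ {label} | {row['group'].capitalize()} | "
                f"{_fmt(row['mean_rq'])} ± {_fmt(row['sd_rq'])} |"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute a full run; returns tables and written paths.

    Artifacts under ``config.out_dir``: metrics.csv, reliability.csv,
    romberg.csv, report.md (per-condition tables plus cohort summary),
    config.json and run.log; optionally the synthetic trials themselves.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("stabilometry")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        logger.info("stabilometry %s, seed=%d", __version__, config.seed)
        if config.manifest is not None:
            trials = read_manifest(config.manifest)
            logger.info("loaded %d trials from %s", len(trials), config.manifest)
        else:
            trials, truth = generate_cohort(config.synthetic)
            logger.info(
                "generated %d synthetic trials (designed ICC %.3f)",
                len(trials),
                truth.designed_icc,
            )
            truth.to_json(out_dir / "ground_truth.json")
            if config.write_trials:
                write_trialset(trials, out_dir / "trials")

        metrics = metrics_table(
            trials,
            m_max=config.m_max,
            n_intervals=config.n_intervals,
            short_window_s=config.short_window_s,
            long_window_s=config.long_window_s,
        )
        metrics_path = out_dir / "metrics.csv"
        metrics.to_csv(metrics_path, index=False)

        rel = reliability_table(metrics, variables=METRIC_COLUMNS, alpha=config.alpha)
        rel_path = out_dir / "reliability.csv"
        rel.to_csv(rel_path, index=False)

        rq = romberg_table(
            metrics, variables=config.rq_variables, pair=config.rq_pair
        )
        rq_path = out_dir / "romberg.csv"
        rq.to_csv(rq_path, index=False)

        report_parts = [
            "# Stabilometric test-retest report",
            "",
            _cohort_summary(metrics, rq),
        ]
        for cond in dict.fromkeys(metrics["condition"]) if not metrics.empty else []:
            report_parts.append(render_condition_table(rel, cond))
        report_path = out_dir / "report.md"
        report_path.write_text("\n".join(report_parts))

        (out_dir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, default=str)
        )
        logger.info("run complete: %d trials, %d reliability rows", len(trials), len(rel))
    finally:
        root.removeHandler(handler)
        handler.close()

    return {
        "trials": trials,
        "metrics": metrics,
        "reliability": rel,
        "romberg": rq,
        "paths": {
            "metrics": metrics_path,
            "reliability": rel_path,
            "romberg": rq_path,
            "report": report_path,
            "log": log_path,
        },
    }
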