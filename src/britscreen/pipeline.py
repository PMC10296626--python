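"""End-to-end pipeline: score -> screen -> evaluate, with file outputs.

The pipeline reads a cohort (or takes simulated records), writes per-patient
scoresheets and referral decisions, and — when reference-standard labels are
available — evaluates the screen against perimetry.  An evaluate-only entry
point accepts a bare 2x2 confusion table, so published accuracy figures can
be reproduced without patient-level data.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .accuracy import (
    AccuracyReport,
    ConfusionCounts,
    evaluate_counts,
    format_report,
    tabulate,
)
from .data import PatientRecord, read_cohort
from .scoring import (
    CutoffTable,
    DEFAULT_CUTOFFS,
    NON_URGENT_REFERRAL,
    URGENT_REFERRAL,
    BritFlags,
    BritScores,
    compute_scores,
    flag_scores,
    scoresheet,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis choices for one pipeline run.

    Defaults reproduce the published analysis: mean-based scoring, Wald
    confidence intervals, 50% assumed prevalence, evaluation restricted to
    neglect patients.
    """

    trials_path: str | None = None
    metadata_path: str | None = None
    output_dir: str | None = None
    cutoffs: CutoffTable = field(default_factory=CutoffTable)
    central_tendency: str = "mean"
    ci_method: str = "wald"
    prevalence: float = 0.5
    restrict_to_neglect: bool = True
    seed: int | None = None


def decision_for(flags: BritFlags) -> str:
    """Referral recommendation: urgent iff the screen is positive."""
    return URGENT_REFERRAL if flags.screening_positive else NON_URGENT_REFERRAL


def score_cohort(
    records: list[PatientRecord], config: PipelineConfig = PipelineConfig()
) -> dict[str, tuple[BritScores, BritFlags]]:
    """Score and flag every patient in the cohort."""
    return {
        record.patient_id: (
            scores := compute_scores(record.trial_set, config.central_tendency),
            flag_scores(scores, config.cutoffs),
        )
        for record in records
    }


def evaluate_cohort(
    records: list[PatientRecord], config: PipelineConfig = PipelineConfig()
) -> tuple[ConfusionCounts, AccuracyReport]:
    """Tabulate screening outcomes against perimetry and compute accuracy.

    By default only neglect (N+) patients enter the 2x2 table, matching the
    screening question (detecting hemi-field deficits *in neglect*); patients
    without battery or reference labels are excluded with a log message.
    """
    scored = score_cohort(records, config)
    cases: list[tuple[bool, bool]] = []
    for record in records:
        if record.reference is None:
            logger.warning("patient %s has no reference standard; excluded", record.patient_id)
            continue
        if config.restrict_to_neglect:
            label = record.neglect_label
            if label is None:
                logger.warning("patient %s has no battery; excluded", record.patient_id)
                continue
            if label == "N-":
                continue
        _, flags = scored[record.patient_id]
        cases.append((record.reference.present, flags.screening_positive))
    counts = tabulate(cases)
    return counts, evaluate_counts(counts, config.prevalence, config.ci_method)


@dataclass(frozen=True)
class PipelineResult:
    scoresheets: pd.DataFrame
    decisions: pd.DataFrame
    counts: ConfusionCounts | None
    report: AccuracyReport | None


def run_pipeline(
    config: PipelineConfig, records: list[PatientRecord] | None = None
) -> PipelineResult:
    """Run score -> screen -> evaluate and (optionally) write all artifacts.

    ``records`` may be passed directly (e.g. a simulated cohort); otherwise
    they are read from ``config.trials_path`` / ``config.metadata_path``.
    The evaluation stage is skipped with a warning when no patient carries a
    reference-standard label.
    """
    if records is None:
        if config.trials_path is None:
            raise ValueError("either records or config.trials_path is required")
        records = read_cohort(config.trials_path, config.metadata_path)

    scored = score_cohort(records, config)

    sheets = []
    decision_rows = []
    for record in records:
        scores, flags = scored[record.patient_id]
        sheet = scoresheet(scores, flags, config.cutoffs)
        sheet.insert(0, "patient_id", record.patient_id)
        sheets.append(sheet)
        decision_rows.append(
            {
                "patient_id": record.patient_id,
                "screening_positive": flags.screening_positive,
                "decision": decision_for(flags),
            }
        )
    scoresheets = pd.concat(sheets, ignore_index=True)
    decisions = pd.DataFrame(decision_rows)

    counts = report = None
    if any(record.reference is not None for record in records):
        counts, report = evaluate_cohort(records, config)
    else:
        logger.warning("no reference-standard labels; evaluation stage skipped")

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        scoresheets.to_csv(out / "scoresheets.csv", index=False)
        decisions.to_csv(out / "decisions.csv", index=False)
        if report is not None:
            _write_report(report, out)
        (out / "run_config.json").write_text(_config_json(config))
        logger.info("pipeline outputs written to %s", out)

    return PipelineResult(scoresheets, decisions, counts, report)


def report_frame(report: AccuracyReport) -> pd.DataFrame:
    """Machine-readable accuracy report (full precision, proportions)."""
    c = report.counts
    rows = [
        ("tp", c.tp, None, None),
        ("fp", c.fp, None, None),
        ("fn", c.fn, None, None),
        ("tn", c.tn, None, None),
        (
            "sensitivity",
            report.sensitivity.value if report.sensitivity else None,
            report.sensitivity.ci_low if report.sensitivity else None,
            report.sensitivity.ci_high if report.sensitivity else None,
        ),
        (
            "specificity",
            report.specificity.value if report.specificity else None,
            report.specificity.ci_low if report.specificity else None,
            report.specificity.ci_high if report.specificity else None,
        ),
        ("ppv", report.ppv, *(report.ppv_ci or (None, None))),
        ("npv", report.npv, *(report.npv_ci or (None, None))),
        ("overall_accuracy", report.overall_accuracy, None, None),
        ("prevalence_assumed", report.prevalence_assumed, None, None),
        ("prevalence_observed", report.prevalence_observed, None, None),
    ]
    return pd.DataFrame(rows, columns=["quantity", "value", "ci_low", "ci_high"])


def _write_report(report: AccuracyReport, out: Path) -> None:
    report_frame(report).to_csv(out / "accuracy.csv", index=False)
    (out / "summary.txt").write_text(format_report(report) + "\n")


def _config_json(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    return json.dumps(payload, indent=2, default=str)
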