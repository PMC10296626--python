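"""Domain types, validation and delimited-text I/O for BRIT cohorts.

The Brentano Illusion Test (BRIT) is a paper-and-pencil line-bisection
instrument: a patient bisects 30 printed lines (5 trials for each of 6
stimulus conditions: 2 line lengths x 3 illusion configurations) and the
examiner records each signed deviation from the true midpoint, in whole
millimetres, negative for leftward and positive for rightward marks.

This module defines the containers for those raw data (trials, trial sets,
neglect-battery scores, the perimetry reference standard, patient records),
the neglect classification rule of the standard battery, and CSV readers and
writers so that a cohort round-trips losslessly through plain text.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# --- stimulus geometry -------------------------------------------------------

LINE_LENGTHS_MM: tuple[int, int] = (80, 160)

NEUTRAL = "neutral"
LEFT_EXPANSION = "left_expansion"
RIGHT_EXPANSION = "right_expansion"
CONFIGURATIONS: tuple[str, str, str] = (NEUTRAL, LEFT_EXPANSION, RIGHT_EXPANSION)

TRIALS_PER_CONDITION = 5
N_CONDITIONS = 6
TRIALS_PER_PATIENT = TRIALS_PER_CONDITION * N_CONDITIONS

# Wing geometry of the Brentano (double Mueller-Lyer) configurations.
# Wings-out (135 deg) produce apparent expansion, wings-in (45 deg) apparent
# contraction; wing segment length scales with the line. Carried as metadata
# only — nothing downstream computes with angles.
WINGS_OUT_ANGLE_DEG = 135.0
WINGS_IN_ANGLE_DEG = 45.0
WING_SEGMENT_MM: Mapping[int, int] = {80: 20, 160: 40}


class ValidationError(ValueError):
    """A cohort, trial set or battery violates a structural invariant."""


@dataclass(frozen=True)
class StimulusCondition:
    """One of the six length x configuration stimulus conditions."""

    length_mm: int
    configuration: str

    def __post_init__(self) -> None:
        if self.length_mm not in LINE_LENGTHS_MM:
            raise ValidationError(
                f"length_mm must be one of {LINE_LENGTHS_MM}, got {self.length_mm!r}"
            )
        if self.configuration not in CONFIGURATIONS:
            raise ValidationError(
                f"configuration must be one of {CONFIGURATIONS}, "
                f"got {self.configuration!r}"
            )

    @property
    def half_length_mm(self) -> float:
        return self.length_mm / 2.0


ALL_CONDITIONS: tuple[StimulusCondition, ...] = tuple(
    StimulusCondition(length, configuration)
    for length in LINE_LENGTHS_MM
    for configuration in CONFIGURATIONS
)


def round_deviation(raw_mm: float) -> int:
    """Round a measured deviation to the nearest whole millimetre.

    Halves round away from zero, matching how an examiner reads a ruler;
    the sign (negative = left of midpoint) is preserved.
    """
    return int(math.copysign(math.floor(abs(raw_mm) + 0.5), raw_mm))


@dataclass(frozen=True)
class BisectionTrial:
    """A single bisection response: condition, trial number, signed deviation.

    ``deviation_mm`` must already be an integer number of millimetres; a mark
    cannot fall outside the line, so ``|deviation_mm| <= length/2``.
    """

    condition: StimulusCondition
    trial_index: int
    deviation_mm: int

    def __post_init__(self) -> None:
        if not (1 <= int(self.trial_index) <= TRIALS_PER_CONDITION):
            raise ValidationError(
                f"trial_index must be in 1..{TRIALS_PER_CONDITION}, "
                f"got {self.trial_index!r}"
            )
        dev = self.deviation_mm
        if isinstance(dev, float) and not dev.is_integer():
            raise ValidationError(
                f"deviation_mm must be a whole number of millimetres, got {dev!r}; "
                "round explicitly with round_deviation() if needed"
            )
        dev = int(dev)
        object.__setattr__(self, "deviation_mm", dev)
        half = self.condition.half_length_mm
        if abs(dev) > half:
            raise ValidationError(
                f"deviation {dev} mm outside the line "
                f"(|deviation| <= {half:g} mm for a {self.condition.length_mm} mm line)"
            )


@dataclass(frozen=True)
class TrialSet:
    """The complete 30-trial BRIT protocol of one patient."""

    patient_id: str
    age_years: float
    trials: tuple[BisectionTrial, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "trials", tuple(self.trials))
        if not self.age_years > 0:
            raise ValidationError(
                f"patient {self.patient_id}: age_years must be positive, "
                f"got {self.age_years!r}"
            )
        by_condition: dict[StimulusCondition, list[BisectionTrial]] = {
            c: [] for c in ALL_CONDITIONS
        }
        for trial in self.trials:
            by_condition[trial.condition].append(trial)
        for condition, trials in by_condition.items():
            if len(trials) != TRIALS_PER_CONDITION:
                raise ValidationError(
                    f"patient {self.patient_id}: condition "
                    f"({condition.length_mm}, {condition.configuration}) "
                    f"has {len(trials)} trials"
                )
            indices = sorted(t.trial_index for t in trials)
            if indices != list(range(1, TRIALS_PER_CONDITION + 1)):
                raise ValidationError(
                    f"patient {self.patient_id}: condition "
                    f"({condition.length_mm}, {condition.configuration}) "
                    f"has duplicate or missing trial indices {indices}"
                )

    def condition_deviations(self, condition: StimulusCondition) -> np.ndarray:
        """The 5 signed deviations of one condition, ordered by trial index."""
        trials = sorted(
            (t for t in self.trials if t.condition == condition),
            key=lambda t: t.trial_index,
        )
        return np.array([t.deviation_mm for t in trials], dtype=float)


# --- neglect battery ---------------------------------------------------------

# (cut-off, direction): a test is failed when `score <direction> cut-off`.
# Directions follow the published battery conventions: cancellation and
# asymmetry scores fail high, target-accuracy and sentence-reading fail low.
BATTERY_TESTS: Mapping[str, tuple[float, str]] = {
    "letter_cancellation": (4, "ge"),
    "star_cancellation": (3, "ge"),
    "line_cancellation": (2, "ge"),
    "apples_accuracy": (44, "le"),
    "apples_space": (3, "ge"),
    "apples_object": (2, "ge"),
    "line_bisection_pct": (6.73, "gt"),
    "wundt_jastrow": (2, "ge"),
    "sentence_reading": (5, "le"),
    "personal_neglect": (2, "ge"),
    "room_description": (1, "ge"),
}

_DIRECTION_OPS = {
    "ge": lambda score, cutoff: score >= cutoff,
    "le": lambda score, cutoff: score <= cutoff,
    "gt": lambda score, cutoff: score > cutoff,
}

NEGLECT_FAILED_TESTS_MIN = 2  # N+ requires failing at least two battery tests


@dataclass(frozen=True)
class BatteryScores:
    """Scores on the eleven standard neglect-battery tests."""

    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(BATTERY_TESTS) - set(self.scores)
        unknown = set(self.scores) - set(BATTERY_TESTS)
        if missing or unknown:
            raise ValidationError(
                f"battery scores must cover exactly {sorted(BATTERY_TESTS)}; "
                f"missing={sorted(missing)}, unknown={sorted(unknown)}"
            )
        for name, value in self.scores.items():
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValidationError(
                    f"battery test {name!r} has an unresolvable score {value!r}"
                )
        object.__setattr__(self, "scores", dict(self.scores))

    def failed(self, test: str) -> bool:
        cutoff, direction = BATTERY_TESTS[test]
        return bool(_DIRECTION_OPS[direction](self.scores[test], cutoff))

    @property
    def n_failed(self) -> int:
        return sum(self.failed(test) for test in BATTERY_TESTS)


def classify_neglect(battery: BatteryScores) -> str:
    """Classify a patient as ``"N+"`` (neglect) or ``"N-"``.

    Neglect is diagnosed when at least two battery tests are failed; failing
    none or one test classifies the patient as not having neglect.
    """
    return "N+" if battery.n_failed >= NEGLECT_FAILED_TESTS_MIN else "N-"


# --- reference standard ------------------------------------------------------

VHFD_ABSENT = "absent"
VHFD_CATEGORIES: tuple[str, ...] = (
    VHFD_ABSENT,
    "hemianopia",
    "quadrantanopia_superior",
    "quadrantanopia_inferior",
)


@dataclass(frozen=True)
class ReferenceStandard:
    """Perimetry outcome (the reference standard) for the left visual field."""

    vhfd: str

    def __post_init__(self) -> None:
        if self.vhfd not in VHFD_CATEGORIES:
            raise ValidationError(
                f"vhfd must be one of {VHFD_CATEGORIES}, got {self.vhfd!r}"
            )

    @property
    def present(self) -> bool:
        return self.vhfd != VHFD_ABSENT

    @property
    def is_hemianopia(self) -> bool:
        return self.vhfd == "hemianopia"


@dataclass
class PatientRecord:
    """One patient: trials plus optional battery, reference standard, and —
    for simulated patients — the generating parameters (``ground_truth``)."""

    trial_set: TrialSet
    battery: BatteryScores | None = None
    reference: ReferenceStandard | None = None
    ground_truth: Mapping[str, object] | None = field(default=None, repr=False)

    @property
    def patient_id(self) -> str:
        return self.trial_set.patient_id

    @property
    def neglect_label(self) -> str | None:
        return classify_neglect(self.battery) if self.battery is not None else None

    @property
    def group(self) -> str | None:
        """Study group label: ``N-``, ``N+H+`` or ``N+H-`` (None if unknown)."""
        neglect = self.neglect_label
        if neglect is None:
            return None
        if neglect == "N-":
            return "N-"
        if self.reference is None:
            return None
        return "N+H+" if self.reference.present else "N+H-"


# --- delimited-text I/O ------------------------------------------------------

TRIAL_COLUMNS = (
    "patient_id",
    "age_years",
    "length_mm",
    "configuration",
    "trial_index",
    "deviation_mm",
)
METADATA_COLUMNS = ("patient_id", *BATTERY_TESTS, "perimetry_outcome")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")


def read_cohort(
    trials_path: str, metadata_path: str | None = None
) -> list[PatientRecord]:
    """Read a cohort from a trials CSV and an optional metadata CSV.

    The trials file has one row per bisection trial (columns
    ``patient_id, age_years, length_mm, configuration, trial_index,
    deviation_mm``); the metadata file has one row per patient with the
    battery-test scores and the perimetry outcome, joined on ``patient_id``.
    Row order never affects the result. Fractional deviations are rejected —
    rounding to whole millimetres is the examiner's responsibility
    (see :func:`round_deviation`).
    """
    df = pd.read_csv(trials_path, dtype={"patient_id": str}, float_precision="round_trip")
    _require_columns(df, TRIAL_COLUMNS, str(trials_path))

    dev_numeric = pd.to_numeric(df["deviation_mm"], errors="coerce")
    bad = df.index[dev_numeric.isna() | (dev_numeric != np.round(dev_numeric))]
    if len(bad):
        row = int(bad[0]) + 2  # header is line 1
        raise ValidationError(
            f"{trials_path}: non-integer deviation_mm "
            f"{df.loc[bad[0], 'deviation_mm']!r} at line {row}"
        )

    metadata: dict[str, tuple[BatteryScores | None, ReferenceStandard | None]] = {}
    if metadata_path is not None:
        meta = pd.read_csv(
            metadata_path, dtype={"patient_id": str}, float_precision="round_trip"
        )
        _require_columns(meta, ("patient_id",), str(metadata_path))
        dup = meta["patient_id"][meta["patient_id"].duplicated()]
        if len(dup):
            raise ValidationError(
                f"{metadata_path}: duplicate patient_id {dup.iloc[0]!r}"
            )
        for _, row in meta.iterrows():
            battery = None
            scores = {t: row[t] for t in BATTERY_TESTS if t in meta.columns}
            if len(scores) == len(BATTERY_TESTS) and not any(
                pd.isna(v) for v in scores.values()
            ):
                battery = BatteryScores({k: float(v) for k, v in scores.items()})
            reference = None
            outcome = row.get("perimetry_outcome")
            if isinstance(outcome, str) and outcome:
                reference = ReferenceStandard(outcome)
            metadata[str(row["patient_id"])] = (battery, reference)

    records: list[PatientRecord] = []
    for patient_id, rows in df.groupby("patient_id", sort=True):
        ages = rows["age_years"].unique()
        if len(ages) != 1:
            raise ValidationError(
                f"patient {patient_id}: inconsistent age_years values {ages.tolist()}"
            )
        trials = tuple(
            BisectionTrial(
                condition=StimulusCondition(int(r.length_mm), str(r.configuration)),
                trial_index=int(r.trial_index),
                deviation_mm=int(r.deviation_mm),
            )
            for r in rows.itertuples()
        )
        trial_set = TrialSet(str(patient_id), float(ages[0]), trials)
        battery, reference = metadata.get(str(patient_id), (None, None))
        records.append(PatientRecord(trial_set, battery, reference))
    logger.info("read %d patients from %s", len(records), trials_path)
    return records


def write_cohort(
    records: Sequence[PatientRecord],
    trials_path: str,
    metadata_path: str | None = None,
) -> None:
    """Write a cohort back to the same delimited layout :func:`read_cohort` uses."""
    rows = [
        {
            "patient_id": rec.patient_id,
            "age_years": rec.trial_set.age_years,
            "length_mm": t.condition.length_mm,
            "configuration": t.condition.configuration,
            "trial_index": t.trial_index,
            "deviation_mm": t.deviation_mm,
        }
        for rec in records
        for t in rec.trial_set.trials
    ]
    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(trials_path, index=False)

    if metadata_path is not None:
        meta_rows = []
        for rec in records:
            row: dict[str, object] = {"patient_id": rec.patient_id}
            if rec.battery is not None:
                row.update(rec.battery.scores)
            if rec.reference is not None:
                row["perimetry_outcome"] = rec.reference.vhfd
            meta_rows.append(row)
        pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS)).to_csv(
            metadata_path, index=False
        )
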