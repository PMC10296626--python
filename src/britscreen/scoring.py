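"""BRIT index computation, cut-off flags and trial-level variability.

Five indexes summarise one patient's 30 bisections:

* ``LB80`` / ``LB160`` — mean (or median) signed deviation on the plain
  80 mm / 160 mm line, rightward positive, expressed both in millimetres and
  as a percentage of the half-length.
* ``LE`` (Length Effect) — ``LB160% - LB80%``: positive when the long line is
  proportionally more right-shifted than the short one.
* ``SIE80`` / ``SIE160`` (Symmetry of the Illusory Effect) — per length,
  ``[left-expansion - plain] + [right-expansion - plain]``.  Symmetric
  sensitivity to the illusion gives values near zero; a patient who fails to
  perceive the left-side expansion (the signature of a left visual hemi-field
  deficit in neglect) loses the leftward term and the score turns strongly
  positive.

A ``Rightward Bias`` flag — SIE exceeding its rightward cut-off on either
line — is the screening-positive signal for a probable visual hemi-field
deficit.  Cut-offs are normative constants (7.8 mm = 19.5% on the short line,
11.8 mm = 14.75% on the long line; LE high/low at +6.7% / −6.5%; LB at
+8.50% / +12.25%).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Callable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import (
    LEFT_EXPANSION,
    LINE_LENGTHS_MM,
    NEUTRAL,
    RIGHT_EXPANSION,
    TRIALS_PER_CONDITION,
    StimulusCondition,
    TrialSet,
    ValidationError,
)

logger = logging.getLogger(__name__)

HIGH_VARIABILITY_COV = 0.50

# flag values
NORMAL = "normal"
RIGHTWARD_BIAS = "rightward_bias"
LEFTWARD_BIAS = "leftward_bias"
HIGH_BIAS = "high_bias"
LOW_BIAS = "low_bias"
BIAS = "bias"

URGENT_REFERRAL = "urgent_referral"
NON_URGENT_REFERRAL = "non_urgent_referral_optional"


def to_percent(deviation_mm: float, length_mm: int) -> float:
    """Convert a signed deviation in mm to a percentage of the half-length."""
    if length_mm not in LINE_LENGTHS_MM:
        raise ValidationError(f"length_mm must be one of {LINE_LENGTHS_MM}")
    return deviation_mm / (length_mm / 2.0) * 100.0


def from_percent(deviation_pct: float, length_mm: int) -> float:
    """Inverse of :func:`to_percent`."""
    if length_mm not in LINE_LENGTHS_MM:
        raise ValidationError(f"length_mm must be one of {LINE_LENGTHS_MM}")
    return deviation_pct / 100.0 * (length_mm / 2.0)


@dataclass(frozen=True)
class CutoffTable:
    """Normative cut-offs for flagging the five indexes.

    SIE cut-offs are stored redundantly in mm and percent; consistency
    (``pct = mm / half_length * 100``) is enforced. The leftward SIE cut-off
    magnitudes are not part of the published norms; by default
    (``sie_left_mirror=True``) they mirror the rightward ones, and explicit
    values can be injected instead.
    """

    sie80_mm: float = 7.8
    sie80_pct: float = 19.5
    sie160_mm: float = 11.8
    sie160_pct: float = 14.75
    lb80_pct: float = 8.50
    lb160_pct: float = 12.25
    le_high_pct: float = 6.7
    le_low_pct: float = -6.5
    sie_left_mirror: bool = True
    sie80_left_pct: float | None = None
    sie160_left_pct: float | None = None

    def __post_init__(self) -> None:
        for mm, pct, length in (
            (self.sie80_mm, self.sie80_pct, 80),
            (self.sie160_mm, self.sie160_pct, 160),
        ):
            if not math.isclose(to_percent(mm, length), pct, abs_tol=1e-9):
                raise ValidationError(
                    f"inconsistent SIE cut-off for the {length} mm line: "
                    f"{mm} mm is {to_percent(mm, length)}%, not {pct}%"
                )
        if self.le_low_pct >= 0 or self.le_high_pct <= 0:
            raise ValidationError("LE cut-offs must straddle zero")

    def sie_left_cutoff_pct(self, length_mm: int) -> float | None:
        """Leftward SIE cut-off (negative percent) for one line, if defined."""
        explicit = self.sie80_left_pct if length_mm == 80 else self.sie160_left_pct
        if explicit is not None:
            return explicit
        if self.sie_left_mirror:
            return -(self.sie80_pct if length_mm == 80 else self.sie160_pct)
        return None


DEFAULT_CUTOFFS = CutoffTable()

# A normative adjustment maps a raw percent score to an age-adjusted one.
# Signature: (value_pct, age_years, index_name) -> adjusted_pct.
NormativeAdjustment = Callable[[float, float, str], float]


def identity_adjustment(value_pct: float, age_years: float, index: str) -> float:
    """No-op normative adjustment (the default; scores pass through raw)."""
    return value_pct


@dataclass(frozen=True)
class BritScores:
    """The five BRIT indexes of one patient, in mm and percent of half-length."""

    lb80_mm: float
    lb80_pct: float
    lb160_mm: float
    lb160_pct: float
    le_pct: float
    sie80_mm: float
    sie80_pct: float
    sie160_mm: float
    sie160_pct: float
    central_tendency: str = "mean"
    age_adjusted: bool = False


@dataclass(frozen=True)
class BritFlags:
    """Cut-off outcomes for the five indexes plus the screening decision."""

    sie80_flag: str
    sie160_flag: str
    le_flag: str
    lb80_flag: str
    lb160_flag: str

    @property
    def screening_positive(self) -> bool:
        """Rightward Bias on either SIE (or both) — probable hemi-field deficit."""
        return RIGHTWARD_BIAS in (self.sie80_flag, self.sie160_flag)


@dataclass(frozen=True)
class ConditionVariability:
    """Trial-to-trial coefficient of variation within one condition."""

    cov: float | None  # None when the condition mean is exactly zero

    @property
    def high_variability(self) -> bool | None:
        if self.cov is None:
            return None
        return self.cov > HIGH_VARIABILITY_COV


def condition_center(deviations: Sequence[float], method: str = "mean") -> float:
    """Central tendency of the five deviations of one condition.

    ``mean`` is the published scoring rule; ``median`` (the 3rd order
    statistic of 5) is the outlier-robust alternative.
    """
    devs = np.asarray(deviations, dtype=float)
    if devs.shape != (TRIALS_PER_CONDITION,):
        raise ValidationError(
            f"expected exactly {TRIALS_PER_CONDITION} deviations, got {devs.shape}"
        )
    if method == "mean":
        return float(np.mean(devs))
    if method == "median":
        return float(np.median(devs))
    raise ValidationError(f"method must be 'mean' or 'median', got {method!r}")


def compute_scores(
    trial_set: TrialSet,
    method: str = "mean",
    adjustment: NormativeAdjustment | None = None,
) -> BritScores:
    """Compute the five BRIT indexes from a validated trial set.

    Percent scores pass through ``adjustment`` (default: identity) before any
    further use; mm values are the exact back-conversion of the adjusted
    percentages, so mm and percent always stay interconvertible. LE is the
    difference of the two adjusted LB percentages.
    """
    adjust = adjustment or identity_adjustment
    age = trial_set.age_years

    centers: dict[tuple[int, str], float] = {}
    for length in LINE_LENGTHS_MM:
        for configuration in (NEUTRAL, LEFT_EXPANSION, RIGHT_EXPANSION):
            devs = trial_set.condition_deviations(
                StimulusCondition(length, configuration)
            )
            centers[(length, configuration)] = condition_center(devs, method)

    def adjusted_pct(raw_mm: float, length: int, index: str) -> float:
        return adjust(to_percent(raw_mm, length), age, index)

    lb80_pct = adjusted_pct(centers[(80, NEUTRAL)], 80, "lb80")
    lb160_pct = adjusted_pct(centers[(160, NEUTRAL)], 160, "lb160")

    sie = {}
    for length in LINE_LENGTHS_MM:
        raw = (centers[(length, LEFT_EXPANSION)] - centers[(length, NEUTRAL)]) + (
            centers[(length, RIGHT_EXPANSION)] - centers[(length, NEUTRAL)]
        )
        sie[length] = adjusted_pct(raw, length, f"sie{length}")

    return BritScores(
        lb80_mm=from_percent(lb80_pct, 80),
        lb80_pct=lb80_pct,
        lb160_mm=from_percent(lb160_pct, 160),
        lb160_pct=lb160_pct,
        le_pct=lb160_pct - lb80_pct,
        sie80_mm=from_percent(sie[80], 80),
        sie80_pct=sie[80],
        sie160_mm=from_percent(sie[160], 160),
        sie160_pct=sie[160],
        central_tendency=method,
        age_adjusted=adjust is not identity_adjustment,
    )


def _sie_flag(value_pct: float, right_cutoff: float, left_cutoff: float | None) -> str:
    if value_pct > right_cutoff:  # strict: a score exactly at cut-off is normal
        return RIGHTWARD_BIAS
    if left_cutoff is not None and value_pct < left_cutoff:
        return LEFTWARD_BIAS
    return NORMAL


def flag_scores(scores: BritScores, cutoffs: CutoffTable = DEFAULT_CUTOFFS) -> BritFlags:
    """Apply the cut-off table to percent scores and return the flags.

    SIE and LE flags require strictly exceeding their cut-off; LB flags use
    ``>=`` (their cut-offs are published as "at or above").
    """
    flags = BritFlags(
        sie80_flag=_sie_flag(
            scores.sie80_pct, cutoffs.sie80_pct, cutoffs.sie_left_cutoff_pct(80)
        ),
        sie160_flag=_sie_flag(
            scores.sie160_pct, cutoffs.sie160_pct, cutoffs.sie_left_cutoff_pct(160)
        ),
        le_flag=(
            HIGH_BIAS
            if scores.le_pct > cutoffs.le_high_pct
            else LOW_BIAS
            if scores.le_pct < cutoffs.le_low_pct
            else NORMAL
        ),
        lb80_flag=BIAS if scores.lb80_pct >= cutoffs.lb80_pct else NORMAL,
        lb160_flag=BIAS if scores.lb160_pct >= cutoffs.lb160_pct else NORMAL,
    )
    logger.debug(
        "flags: SIE80=%.2f%%->%s SIE160=%.2f%%->%s LE=%.2f%%->%s "
        "LB80=%.2f%%->%s LB160=%.2f%%->%s screening_positive=%s",
        scores.sie80_pct, flags.sie80_flag,
        scores.sie160_pct, flags.sie160_flag,
        scores.le_pct, flags.le_flag,
        scores.lb80_pct, flags.lb80_flag,
        scores.lb160_pct, flags.lb160_flag,
        flags.screening_positive,
    )
    return flags


def condition_cov(deviations: Sequence[float]) -> ConditionVariability:
    """Coefficient of variation (sample SD / |mean|) of one condition's trials.

    Undefined (``cov=None``) when the mean is exactly zero — never an
    infinity or a division error.
    """
    devs = np.asarray(deviations, dtype=float)
    if devs.shape != (TRIALS_PER_CONDITION,):
        raise ValidationError(
            f"expected exactly {TRIALS_PER_CONDITION} deviations, got {devs.shape}"
        )
    mean = float(np.mean(devs))
    if mean == 0.0:
        return ConditionVariability(cov=None)
    return ConditionVariability(cov=float(np.std(devs, ddof=1)) / abs(mean))


def trial_set_cov(trial_set: TrialSet) -> dict[StimulusCondition, ConditionVariability]:
    """Per-condition CoV for all six conditions of one patient."""
    return {
        condition: condition_cov(trial_set.condition_deviations(condition))
        for condition in (
            StimulusCondition(length, configuration)
            for length in LINE_LENGTHS_MM
            for configuration in (NEUTRAL, LEFT_EXPANSION, RIGHT_EXPANSION)
        )
    }


def scoresheet(
    scores: BritScores,
    flags: BritFlags,
    cutoffs: CutoffTable = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Per-patient scoresheet: one row per index with value, cut-off and flag."""
    rows = [
        ("LB80", scores.lb80_mm, scores.lb80_pct, cutoffs.lb80_pct, flags.lb80_flag),
        ("LB160", scores.lb160_mm, scores.lb160_pct, cutoffs.lb160_pct, flags.lb160_flag),
        ("LE", math.nan, scores.le_pct, cutoffs.le_high_pct, flags.le_flag),
        ("SIE80", scores.sie80_mm, scores.sie80_pct, cutoffs.sie80_pct, flags.sie80_flag),
        ("SIE160", scores.sie160_mm, scores.sie160_pct, cutoffs.sie160_pct, flags.sie160_flag),
    ]
    return pd.DataFrame(
        rows, columns=["index", "value_mm", "value_pct", "cutoff_pct", "flag"]
    )
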