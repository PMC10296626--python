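"""Synthetic bisection-behavior cohorts with known ground truth.

No patient-level BRIT data are publicly deposited, so every downstream stage
is exercised against simulated cohorts.  The generative model is the minimal
additive structure consistent with the test's rationale:

    deviation_mm = round( (bias(L) + shift(config)) / 100 * L/2 + eps )

where ``bias(L)`` is the patient's baseline rightward bisection bias on the
plain line of length ``L`` (percent of half-length), ``shift`` is the
illusion-induced displacement — zero for the plain line, ``-a * delta_left``
under left expansion and ``+delta_right`` under right expansion — and
``eps ~ Normal(0, noise_sd)`` is trial-to-trial noise.  The attenuation
``a`` in [0, 1] models how much of the left-side illusion the patient
perceives: 1 with an intact field, 0 under hemianopia (fully suppressed),
0.5 under quadrantanopia (partial, an assumption).  Deviations are rounded
to whole millimetres after noise and clipped to the line.

Default group-level parameter distributions are calibrated so that simulated
score means and SDs approximate the observed group summaries of the study
population (e.g. N+H+ SIE80 ~ +28.7% mean, N- ~ -2.5%), including the high
trial-to-trial variability (CoV > 0.5) characteristic of neglect.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import (
    ALL_CONDITIONS,
    BATTERY_TESTS,
    TRIALS_PER_CONDITION,
    BatteryScores,
    BisectionTrial,
    LEFT_EXPANSION,
    NEUTRAL,
    PatientRecord,
    ReferenceStandard,
    RIGHT_EXPANSION,
    StimulusCondition,
    TrialSet,
    classify_neglect,
    round_deviation,
)
from .scoring import (
    CutoffTable,
    DEFAULT_CUTOFFS,
    compute_scores,
    flag_scores,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BehaviorParams:
    """Per-patient generative parameters, all in percent of half-length.

    Illusion shift magnitudes are per line length because empirically the
    illusory effect does not scale exactly proportionally with line length
    (group SIE percentages differ between the 80 and 160 mm lines).
    """

    bias80_pct: float = 0.0
    bias160_pct: float = 0.0
    delta_left80_pct: float = 0.0
    delta_right80_pct: float = 0.0
    delta_left160_pct: float = 0.0
    delta_right160_pct: float = 0.0
    vhfd_attenuation: float = 1.0
    noise_sd_pct: float = 0.0
    # heavy-tailed contamination: with probability `outlier_prob` a trial's
    # noise SD is inflated by `outlier_scale` (emulates outlying responses;
    # off by default, used for mean-vs-median experiments)
    outlier_prob: float = 0.0
    outlier_scale: float = 5.0

    def __post_init__(self) -> None:
        for name in (
            "delta_left80_pct",
            "delta_right80_pct",
            "delta_left160_pct",
            "delta_right160_pct",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.vhfd_attenuation <= 1.0:
            raise ValueError("vhfd_attenuation must be in [0, 1]")
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")
        if not 0.0 <= self.outlier_prob <= 1.0:
            raise ValueError("outlier_prob must be in [0, 1]")
        if self.outlier_scale < 1.0:
            raise ValueError("outlier_scale must be >= 1")

    def bias_pct(self, length_mm: int) -> float:
        return self.bias80_pct if length_mm == 80 else self.bias160_pct

    def deltas_pct(self, length_mm: int) -> tuple[float, float]:
        if length_mm == 80:
            return self.delta_left80_pct, self.delta_right80_pct
        return self.delta_left160_pct, self.delta_right160_pct

    def shift_pct(self, condition: StimulusCondition) -> float:
        delta_left, delta_right = self.deltas_pct(condition.length_mm)
        if condition.configuration == LEFT_EXPANSION:
            return -self.vhfd_attenuation * delta_left
        if condition.configuration == RIGHT_EXPANSION:
            return delta_right
        return 0.0

    def expected_sie_pct(self, length_mm: int) -> float:
        """Noise-free SIE of this patient (the neutral bias cancels)."""
        delta_left, delta_right = self.deltas_pct(length_mm)
        return delta_right - self.vhfd_attenuation * delta_left


@dataclass(frozen=True)
class ParamPrior:
    """Normal prior for one scalar parameter, truncated by clipping."""

    mean: float
    sd: float
    lower: float | None = None
    upper: float | None = None

    def draw(self, rng: np.random.Generator) -> float:
        value = rng.normal(self.mean, self.sd)
        if self.lower is not None:
            value = max(self.lower, value)
        if self.upper is not None:
            value = min(self.upper, value)
        return float(value)


@dataclass(frozen=True)
class GroupSpec:
    """Generative description of one study group."""

    name: str
    n: int
    age: ParamPrior
    behavior: Mapping[str, ParamPrior]
    battery: Mapping[str, ParamPrior]
    vhfd_mix: Mapping[str, float]
    attenuation_by_vhfd: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")
        total = sum(self.vhfd_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"vhfd_mix proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic cohort: ordered groups plus the base seed."""

    groups: tuple[GroupSpec, ...]
    seed: int = 0

    @property
    def n_total(self) -> int:
        return sum(g.n for g in self.groups)


_BEHAVIOR_FIELDS = (
    "bias80_pct",
    "bias160_pct",
    "delta_left80_pct",
    "delta_right80_pct",
    "delta_left160_pct",
    "delta_right160_pct",
    "noise_sd_pct",
)

# Plausible score ranges used to clip drawn battery values.
_BATTERY_RANGES: Mapping[str, tuple[float, float]] = {
    "letter_cancellation": (0, 53),
    "star_cancellation": (0, 27),
    "line_cancellation": (0, 18),
    "apples_accuracy": (0, 50),
    "apples_space": (0, 25),
    "apples_object": (0, 50),
    "line_bisection_pct": (-100, 100),
    "wundt_jastrow": (0, 24),
    "sentence_reading": (0, 6),
    "personal_neglect": (0, 6),
    "room_description": (0, 6),
}


def _battery_priors(values: Sequence[tuple[float, float]]) -> dict[str, ParamPrior]:
    return {
        name: ParamPrior(mean, sd, *_BATTERY_RANGES[name])
        for (name, (mean, sd)) in zip(BATTERY_TESTS, values)
    }


def default_cohort_spec(
    n_nphp: int = 23, n_nphm: int = 22, n_nm: int = 19, seed: int = 0
) -> CohortSpec:
    """The default three-group cohort (N+H+, N+H-, N-), sized like the study
    sample (23 / 22 / 19) and calibrated to its group-level summaries."""
    nphp = GroupSpec(
        name="N+H+",
        n=n_nphp,
        age=ParamPrior(57.4, 13.5, lower=18),
        behavior={
            "bias80_pct": ParamPrior(9.7, 20.0),
            "bias160_pct": ParamPrior(24.5, 25.0),
            "delta_left80_pct": ParamPrior(32.0, 15.0, lower=0),
            "delta_right80_pct": ParamPrior(32.0, 15.0, lower=0),
            "delta_left160_pct": ParamPrior(24.0, 15.0, lower=0),
            "delta_right160_pct": ParamPrior(24.0, 15.0, lower=0),
            "noise_sd_pct": ParamPrior(12.0, 3.0, lower=1.0),
        },
        battery=_battery_priors(
            [
                (20.3, 12.1), (10.7, 8.8), (4.4, 3.8), (19.6, 14.2),
                (9.3, 6.1), (11.0, 11.3), (33.0, 28.2), (11.5, 7.8),
                (2.2, 2.6), (1.5, 1.8), (1.4, 1.2),
            ]
        ),
        # 18 hemianopias, 4 inferior and 1 superior quadrantanopia out of 23
        vhfd_mix={
            "hemianopia": 18 / 23,
            "quadrantanopia_inferior": 4 / 23,
            "quadrantanopia_superior": 1 / 23,
        },
        attenuation_by_vhfd=DEFAULT_ATTENUATION,
    )
    nphm = GroupSpec(
        name="N+H-",
        n=n_nphm,
        age=ParamPrior(64.5, 12.0, lower=18),
        behavior={
            "bias80_pct": ParamPrior(1.0, 8.5),
            "bias160_pct": ParamPrior(5.1, 6.0),
            "delta_left80_pct": ParamPrior(16.6, 5.0, lower=0),
            "delta_right80_pct": ParamPrior(15.0, 5.0, lower=0),
            "delta_left160_pct": ParamPrior(14.5, 6.0, lower=0),
            "delta_right160_pct": ParamPrior(14.0, 6.0, lower=0),
            "noise_sd_pct": ParamPrior(12.0, 3.0, lower=1.0),
        },
        battery=_battery_priors(
            [
                (17.8, 16.6), (10.0, 9.9), (1.0, 2.1), (25.2, 15.2),
                (8.8, 7.3), (6.1, 10.1), (9.4, 10.6), (6.0, 7.2),
                (4.8, 1.8), (2.2, 2.2), (1.5, 1.2),
            ]
        ),
        vhfd_mix={"absent": 1.0},
        attenuation_by_vhfd=DEFAULT_ATTENUATION,
    )
    nm = GroupSpec(
        name="N-",
        n=n_nm,
        age=ParamPrior(64.9, 14.1, lower=18),
        behavior={
            "bias80_pct": ParamPrior(1.1, 2.0),
            "bias160_pct": ParamPrior(1.4, 3.0),
            "delta_left80_pct": ParamPrior(13.0, 2.0, lower=0),
            "delta_right80_pct": ParamPrior(10.5, 2.0, lower=0),
            "delta_left160_pct": ParamPrior(12.0, 2.5, lower=0),
            "delta_right160_pct": ParamPrior(11.8, 2.5, lower=0),
            "noise_sd_pct": ParamPrior(4.0, 1.0, lower=0.5),
        },
        battery=_battery_priors(
            [
                (1.0, 1.9), (0.4, 0.9), (0.0, 0.5), (46.0, 10.4),
                (0.1, 0.9), (0.4, 1.3), (2.3, 3.5), (0.2, 0.5),
                (6.0, 0.3), (0.2, 0.7), (0.1, 0.2),
            ]
        ),
        vhfd_mix={"absent": 1.0},
        attenuation_by_vhfd=DEFAULT_ATTENUATION,
    )
    return CohortSpec(groups=(nphp, nphm, nm), seed=seed)


# Left-illusion attenuation by perimetry outcome: an intact field perceives
# the illusion fully (1), hemianopia suppresses it (0), quadrantanopia
# partially (0.5, an assumption — quadrantanopias are detected less reliably).
DEFAULT_ATTENUATION: Mapping[str, float] = {
    "absent": 1.0,
    "hemianopia": 0.0,
    "quadrantanopia_superior": 0.5,
    "quadrantanopia_inferior": 0.5,
}


def expected_deviation_mm(params: BehaviorParams, condition: StimulusCondition) -> float:
    """Noise-free model mean of one trial, in mm (before integer rounding)."""
    pct = params.bias_pct(condition.length_mm) + params.shift_pct(condition)
    return pct / 100.0 * condition.half_length_mm


def simulate_trial(
    params: BehaviorParams,
    condition: StimulusCondition,
    trial_index: int,
    rng: np.random.Generator,
) -> BisectionTrial:
    """Draw one bisection trial: model mean plus Gaussian noise, rounded to
    whole millimetres and clipped to the line."""
    half = condition.half_length_mm
    sd_mm = params.noise_sd_pct / 100.0 * half
    if params.outlier_prob > 0.0 and rng.random() < params.outlier_prob:
        sd_mm *= params.outlier_scale
    noise_mm = rng.normal(0.0, sd_mm)
    raw = expected_deviation_mm(params, condition) + noise_mm
    deviation = round_deviation(raw)
    deviation = int(np.clip(deviation, -half, half))
    return BisectionTrial(condition=condition, trial_index=trial_index, deviation_mm=deviation)


def simulate_trial_set(
    params: BehaviorParams,
    patient_id: str,
    age_years: float,
    rng: np.random.Generator,
) -> TrialSet:
    """The full 30-trial protocol of one simulated patient."""
    trials = tuple(
        simulate_trial(params, condition, index, rng)
        for condition in ALL_CONDITIONS
        for index in range(1, TRIALS_PER_CONDITION + 1)
    )
    return TrialSet(patient_id=patient_id, age_years=age_years, trials=trials)


def _draw_battery(
    group: GroupSpec, rng: np.random.Generator
) -> BatteryScores:
    """Draw battery scores from the group priors and force label consistency.

    Scores are drawn per test; integer-valued tests are rounded. If the drawn
    profile would contradict the group's neglect label, the minimal edit is
    applied: neglect groups get their two cancellation scores pushed past
    cut-off, non-neglect groups get failing scores pulled just inside it.
    """
    scores: dict[str, float] = {}
    for name, prior in group.battery.items():
        value = prior.draw(rng)
        if name != "line_bisection_pct":
            value = float(round(value))
            lo, hi = _BATTERY_RANGES[name]
            value = float(np.clip(value, lo, hi))
        scores[name] = value

    neglect_group = group.name.startswith("N+")
    battery = BatteryScores(scores)
    if neglect_group and battery.n_failed < 2:
        scores["letter_cancellation"] = max(scores["letter_cancellation"], 6.0)
        scores["star_cancellation"] = max(scores["star_cancellation"], 5.0)
        battery = BatteryScores(scores)
    elif not neglect_group and battery.n_failed >= 2:
        passing = {
            "letter_cancellation": 0.0, "star_cancellation": 0.0,
            "line_cancellation": 0.0, "apples_accuracy": 46.0,
            "apples_space": 0.0, "apples_object": 0.0,
            "line_bisection_pct": 1.0, "wundt_jastrow": 0.0,
            "sentence_reading": 6.0, "personal_neglect": 0.0,
            "room_description": 0.0,
        }
        for name in BATTERY_TESTS:
            if battery.failed(name):
                scores[name] = passing[name]
        battery = BatteryScores(scores)
    assert classify_neglect(battery) == ("N+" if neglect_group else "N-")
    return battery


def simulate_patient(
    group: GroupSpec, patient_id: str, rng: np.random.Generator
) -> PatientRecord:
    """Draw one patient: age, perimetry outcome, behavior, battery, trials."""
    age = group.age.draw(rng)
    vhfd_types = sorted(group.vhfd_mix)
    probabilities = np.array([group.vhfd_mix[t] for t in vhfd_types])
    vhfd = str(rng.choice(vhfd_types, p=probabilities / probabilities.sum()))
    drawn = {name: group.behavior[name].draw(rng) for name in _BEHAVIOR_FIELDS}
    params = BehaviorParams(
        vhfd_attenuation=group.attenuation_by_vhfd[vhfd], **drawn
    )
    battery = _draw_battery(group, rng)
    trial_set = simulate_trial_set(params, patient_id, age, rng)
    return PatientRecord(
        trial_set=trial_set,
        battery=battery,
        reference=ReferenceStandard(vhfd),
        ground_truth={"group": group.name, "vhfd": vhfd, "params": params},
    )


_GROUP_ID_PREFIX = {"N+H+": "NpHp", "N+H-": "NpHm", "N-": "Nm"}


def simulate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> list[PatientRecord]:
    """Simulate a full cohort; reproducible given the seed (``spec.seed``
    unless overridden)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[PatientRecord] = []
    for group in spec.groups:
        prefix = _GROUP_ID_PREFIX.get(group.name, group.name)
        for i in range(1, group.n + 1):
            records.append(simulate_patient(group, f"{prefix}-{i:02d}", rng))
    logger.info(
        "simulated cohort of %d patients (%s)",
        len(records),
        ", ".join(f"{g.name}: {g.n}" for g in spec.groups),
    )
    return records


# --- closed-form screening probabilities and parameter recovery -------------

# Variance added to a SIE score by rounding each trial to whole millimetres,
# treating the rounding error as uniform on (-1/2, 1/2) mm: the SIE combines
# six condition centers (each a mean of 5 trials) with weights (1, 1, -2).
_QUANTIZATION_VAR_MM2 = 6.0 * (1.0 / 12.0) / TRIALS_PER_CONDITION


def flag_probability(
    params: BehaviorParams, cutoffs: CutoffTable = DEFAULT_CUTOFFS
) -> float:
    """Probability that a patient with these parameters screens positive.

    Under the Gaussian model the SIE percentage for length L is normal with
    mean ``delta_right - attenuation * delta_left`` and variance
    ``6/5 * noise_sd^2`` (three condition centers with weights 1, 1, -2, each
    a mean of five trials) plus the millimetre-quantization term; the two
    lengths use disjoint trials, so
    ``P(positive) = 1 - P(SIE80 <= cut80) * P(SIE160 <= cut160)``.
    Clipping at the line ends is ignored (negligible for realistic
    parameters), and the pure-Gaussian noise model is assumed
    (``outlier_prob = 0``).
    """
    p_not_flagged = 1.0
    for length, cutoff in ((80, cutoffs.sie80_pct), (160, cutoffs.sie160_pct)):
        mu = params.expected_sie_pct(length)
        half = length / 2.0
        var_pct = (6.0 / TRIALS_PER_CONDITION) * params.noise_sd_pct**2
        var_pct += _QUANTIZATION_VAR_MM2 * (100.0 / half) ** 2
        sd = np.sqrt(var_pct)
        if sd == 0.0:
            p_not_flagged *= 1.0 if mu <= cutoff else 0.0
        else:
            p_not_flagged *= float(norm.cdf((cutoff - mu) / sd))
    return 1.0 - p_not_flagged


def screening_outcomes(
    records: Sequence[PatientRecord],
    cutoffs: CutoffTable = DEFAULT_CUTOFFS,
    method: str = "mean",
) -> pd.DataFrame:
    """Score and flag every patient; one row per patient with disease status,
    screening outcome and (for simulated patients) the oracle probability."""
    rows = []
    for record in records:
        flags = flag_scores(compute_scores(record.trial_set, method), cutoffs)
        truth = record.ground_truth or {}
        params = truth.get("params")
        rows.append(
            {
                "patient_id": record.patient_id,
                "group": truth.get("group", record.group),
                "disease_present": (
                    record.reference.present if record.reference else None
                ),
                "screening_positive": flags.screening_positive,
                "oracle_p_positive": (
                    flag_probability(params, cutoffs) if params is not None else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def recovery_experiment(
    spec: CohortSpec,
    n_replicates: int,
    seed: int,
    cutoffs: CutoffTable = DEFAULT_CUTOFFS,
    method: str = "mean",
) -> pd.DataFrame:
    """Monte-Carlo distribution of estimated sensitivity and specificity.

    Each replicate simulates a cohort, runs the full score -> flag -> tabulate
    pipeline over the neglect (N+) patients, and records the estimated
    sensitivity and specificity next to their closed-form expectations (the
    mean per-patient Gaussian flag probability, :func:`flag_probability`).
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    rows = []
    for replicate, child in enumerate(child_seeds):
        cohort = simulate_cohort(spec, seed=int(child) % 2**31)
        outcomes = screening_outcomes(cohort, cutoffs, method)
        neglect = outcomes[outcomes["group"] != "N-"]
        diseased = neglect[neglect["disease_present"]]
        healthy = neglect[~neglect["disease_present"]]
        rows.append(
            {
                "replicate": replicate,
                "sensitivity": diseased["screening_positive"].mean(),
                "specificity": 1.0 - healthy["screening_positive"].mean(),
                "oracle_sensitivity": diseased["oracle_p_positive"].mean(),
                "oracle_specificity": 1.0 - healthy["oracle_p_positive"].mean(),
            }
        )
    return pd.DataFrame(rows)


def with_attenuation(spec: CohortSpec, attenuation: float) -> CohortSpec:
    """Copy of ``spec`` with every non-intact perimetry outcome mapped to one
    fixed attenuation value (intact fields keep attenuation 1).

    Because attenuation enters the model deterministically given the drawn
    perimetry outcome, simulating the modified spec with the same seed reuses
    identical random draws — common random numbers across attenuation levels.
    """
    groups = []
    for group in spec.groups:
        mapping = {
            vhfd: (1.0 if vhfd == "absent" else attenuation)
            for vhfd in group.attenuation_by_vhfd
        }
        groups.append(replace(group, attenuation_by_vhfd=mapping))
    return CohortSpec(groups=tuple(groups), seed=spec.seed)
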