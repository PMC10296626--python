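from __future__ import annotations

from collections.abc import Mapping, Sequence

import pytest

from britscreen import (
    ALL_CONDITIONS,
    BATTERY_TESTS,
    BatteryScores,
    BisectionTrial,
    StimulusCondition,
    TrialSet,
)


def make_trial_set(
    deviations: Mapping[tuple[int, str], Sequence[int] | int] | None = None,
    patient_id: str = "p1",
    age: float = 60.0,
) -> TrialSet:
    """Build a valid 30-trial set; unspecified conditions default to zeros.

    ``deviations`` maps ``(length_mm, configuration)`` to five integers (or a
    single integer applied to all five trials).
    """
    deviations = deviations or {}
    trials = []
    for condition in ALL_CONDITIONS:
        values = deviations.get((condition.length_mm, condition.configuration), 0)
        if isinstance(values, int):
            values = [values] * 5
        assert len(values) == 5
        trials.extend(
            BisectionTrial(condition, index, value)
            for index, value in enumerate(values, start=1)
        )
    return TrialSet(patient_id=patient_id, age_years=age, trials=tuple(trials))


def make_battery(n_failed: int = 0) -> BatteryScores:
    """Battery scores failing exactly ``n_failed`` tests (failed in order)."""
    passing = {
        "letter_cancellation": 0.0, "star_cancellation": 0.0,
        "line_cancellation": 0.0, "apples_accuracy": 46.0,
        "apples_space": 0.0, "apples_object": 0.0,
        "line_bisection_pct": 1.0, "wundt_jastrow": 0.0,
        "sentence_reading": 6.0, "personal_neglect": 0.0,
        "room_description": 0.0,
    }
    failing = {
        "letter_cancellation": 10.0, "star_cancellation": 8.0,
        "line_cancellation": 4.0, "apples_accuracy": 20.0,
        "apples_space": 6.0, "apples_object": 5.0,
        "line_bisection_pct": 20.0, "wundt_jastrow": 6.0,
        "sentence_reading": 2.0, "personal_neglect": 3.0,
        "room_description": 2.0,
    }
    scores = dict(passing)
    for name in list(BATTERY_TESTS)[:n_failed]:
        scores[name] = failing[name]
    return BatteryScores(scores)


@pytest.fixture
def zero_trial_set() -> TrialSet:
    return make_trial_set()


@pytest.fixture
def condition_80_neutral() -> StimulusCondition:
    return StimulusCondition(80, "neutral")
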