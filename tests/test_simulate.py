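"""The synthetic-cohort generator: model arithmetic, determinism,
calibration, and agreement with its closed-form screening probabilities."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from britscreen import (
    BehaviorParams,
    CohortSpec,
    StimulusCondition,
    compute_scores,
    default_cohort_spec,
    expected_deviation_mm,
    flag_probability,
    flag_scores,
    recovery_experiment,
    screening_outcomes,
    simulate_cohort,
    simulate_trial,
    simulate_trial_set,
    trial_set_cov,
    with_attenuation,
)


def rng(seed=0):
    return np.random.default_rng(seed)


def noiseless(**kwargs) -> BehaviorParams:
    return BehaviorParams(noise_sd_pct=0.0, **kwargs)


def separable_spec(seed=0) -> CohortSpec:
    """Noiseless cohort whose groups are perfectly separated by the cut-offs:
    suppressed left illusion well above cut-off for every diseased patient,
    symmetric illusion sensitivity for everyone else."""
    spec = default_cohort_spec(seed=seed)
    groups = []
    for group in spec.groups:
        behavior = dict(group.behavior)
        for name in behavior:
            mean = {"noise_sd_pct": 0.0}.get(name)
            if mean is None:
                mean = 30.0 if name.startswith("delta") else 0.0
            behavior[name] = dataclasses.replace(behavior[name], mean=mean, sd=0.0)
        groups.append(
            dataclasses.replace(
                group,
                behavior=behavior,
                attenuation_by_vhfd={
                    k: (1.0 if k == "absent" else 0.0)
                    for k in group.attenuation_by_vhfd
                },
            )
        )
    return CohortSpec(groups=tuple(groups), seed=seed)


class TestTrialModel:
    def test_symmetric_deltas_give_zero_sie(self):
        params = noiseless(
            delta_left80_pct=25, delta_right80_pct=25,
            delta_left160_pct=25, delta_right160_pct=25,
        )
        trial_set = simulate_trial_set(params, "p", 60, rng())
        scores = compute_scores(trial_set)
        assert scores.sie80_pct == pytest.approx(0.0)
        assert scores.sie160_pct == pytest.approx(0.0)

    def test_suppressed_left_illusion_forces_sie(self):
        """With attenuation 0 and a 30% right-expansion shift, the SIE on the
        short line is exactly the right-side shift: +12 mm = 30%."""
        params = noiseless(
            delta_left80_pct=30, delta_right80_pct=30, vhfd_attenuation=0.0
        )
        trial_set = simulate_trial_set(params, "p", 60, rng())
        scores = compute_scores(trial_set)
        assert scores.sie80_mm == pytest.approx(12.0)
        assert scores.sie80_pct == pytest.approx(30.0)
        assert flag_scores(scores).screening_positive

    def test_neutral_bias_anchor(self):
        """A 24.5% rightward bias on the long plain line corresponds to a
        19.6 mm model-mean deviation (rounded to 20 mm on the sheet)."""
        params = noiseless(bias160_pct=24.5)
        condition = StimulusCondition(160, "neutral")
        assert expected_deviation_mm(params, condition) == pytest.approx(19.6)
        trial = simulate_trial(params, condition, 1, rng())
        assert trial.deviation_mm == 20

    def test_trials_are_clipped_to_the_line(self):
        params = BehaviorParams(bias80_pct=95.0, noise_sd_pct=40.0)
        devs = [
            simulate_trial(params, StimulusCondition(80, "neutral"), 1, rng(i)).deviation_mm
            for i in range(50)
        ]
        assert max(devs) <= 40 and min(devs) >= -40

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BehaviorParams(vhfd_attenuation=1.5)
        with pytest.raises(ValueError):
            BehaviorParams(delta_left80_pct=-1)
        with pytest.raises(ValueError):
            BehaviorParams(outlier_prob=2.0)

    def test_contamination_inflates_spread_but_not_the_median(self):
        """Heavy-tailed contamination widens mean-based condition centers
        while leaving the median-based centers comparatively stable."""
        clean = BehaviorParams(bias80_pct=10.0, noise_sd_pct=5.0)
        dirty = BehaviorParams(
            bias80_pct=10.0, noise_sd_pct=5.0, outlier_prob=0.2, outlier_scale=8.0
        )
        condition = StimulusCondition(80, "neutral")
        centers = {}
        for label, params in (("clean", clean), ("dirty", dirty)):
            generator = rng(123)
            means, medians = [], []
            for _ in range(400):
                devs = [
                    simulate_trial(params, condition, i, generator).deviation_mm
                    for i in range(1, 6)
                ]
                means.append(np.mean(devs))
                medians.append(np.median(devs))
            centers[label] = (np.std(means), np.std(medians))
        assert centers["dirty"][0] > 1.5 * centers["clean"][0]
        assert centers["dirty"][1] < 1.5 * centers["dirty"][0]


class TestCohort:
    def test_default_cohort_structure(self):
        records = simulate_cohort(default_cohort_spec(seed=4))
        assert len(records) == 64
        assert sum(r.reference.present for r in records) == 23
        groups = pd.Series([r.ground_truth["group"] for r in records]).value_counts()
        assert groups.to_dict() == {"N+H+": 23, "N+H-": 22, "N-": 19}

    def test_labels_are_internally_consistent(self):
        for record in simulate_cohort(default_cohort_spec(seed=4)):
            assert record.group == record.ground_truth["group"]
            assert record.reference.present == (record.ground_truth["group"] == "N+H+")

    def test_empty_cohort(self):
        assert simulate_cohort(default_cohort_spec(0, 0, 0)) == []

    def test_same_seed_reproduces_cohort(self):
        spec = default_cohort_spec(seed=9)
        first = simulate_cohort(spec)
        second = simulate_cohort(spec)
        for a, b in zip(first, second):
            assert a.trial_set == b.trial_set
            assert a.battery.scores == b.battery.scores
            assert a.reference == b.reference

    def test_group_score_calibration(self):
        """Pooled simulated group means land near the study's group-level
        score summaries (percent scale)."""
        rows = []
        for seed in range(8):
            for record in simulate_cohort(default_cohort_spec(seed=seed)):
                scores = compute_scores(record.trial_set)
                rows.append(
                    {
                        "group": record.ground_truth["group"],
                        "sie80": scores.sie80_pct,
                        "sie160": scores.sie160_pct,
                        "lb160": scores.lb160_pct,
                    }
                )
        means = pd.DataFrame(rows).groupby("group").mean()
        assert means.loc["N+H+", "sie80"] == pytest.approx(28.7, abs=6)
        assert means.loc["N+H+", "sie160"] == pytest.approx(21.6, abs=6)
        assert means.loc["N+H+", "lb160"] == pytest.approx(24.5, abs=6)
        assert means.loc["N+H-", "sie80"] == pytest.approx(-1.6, abs=5)
        assert means.loc["N-", "sie80"] == pytest.approx(-2.5, abs=3)

    def test_neglect_groups_show_high_trial_variability(self):
        """Mean per-condition CoV across simulated neglect patients exceeds
        0.5 for at least 5 of the 6 stimulus conditions."""
        covs: dict[tuple[int, str], list[float]] = {}
        for record in simulate_cohort(default_cohort_spec(seed=3)):
            if record.ground_truth["group"] == "N-":
                continue
            for condition, v in trial_set_cov(record.trial_set).items():
                if v.cov is not None:
                    covs.setdefault(
                        (condition.length_mm, condition.configuration), []
                    ).append(v.cov)
        high = sum(np.mean(values) > 0.5 for values in covs.values())
        assert high >= 5


class TestRecovery:
    def test_noiseless_separable_cohort_is_classified_perfectly(self):
        outcomes = screening_outcomes(simulate_cohort(separable_spec(seed=1)))
        neglect = outcomes[outcomes.group != "N-"]
        assert neglect[neglect.disease_present].screening_positive.all()
        assert not neglect[~neglect.disease_present].screening_positive.any()

    def test_fully_perceived_illusion_never_screens_positive(self):
        spec = with_attenuation(separable_spec(seed=1), 1.0)
        outcomes = screening_outcomes(simulate_cohort(spec))
        assert not outcomes.screening_positive.any()

    def test_sensitivity_monotone_in_attenuation(self):
        """Under common random numbers, weakening the left-illusion
        suppression never increases sensitivity."""
        spec = default_cohort_spec(seed=11)
        estimates = []
        for attenuation in (0.0, 0.25, 0.5, 0.75, 1.0):
            cohort = simulate_cohort(with_attenuation(spec, attenuation), seed=5)
            outcomes = screening_outcomes(cohort)
            diseased = outcomes[outcomes.disease_present.astype(bool)]
            estimates.append(diseased.screening_positive.mean())
        assert all(a >= b for a, b in zip(estimates, estimates[1:]))
        assert estimates[0] > estimates[-1]

    def test_flag_probability_monotone_in_noise(self):
        """More trial noise can only push a symmetric (healthy) responder's
        tail probability over the cut-off more often."""
        probabilities = [
            flag_probability(
                BehaviorParams(
                    delta_left80_pct=15, delta_right80_pct=15,
                    delta_left160_pct=15, delta_right160_pct=15,
                    noise_sd_pct=noise,
                )
            )
            for noise in (1, 5, 10, 20)
        ]
        assert all(a <= b for a, b in zip(probabilities, probabilities[1:]))

    def test_monte_carlo_matches_gaussian_oracle_on_one_parameter_set(self):
        """The empirical positive rate of many identical patients sits inside
        the binomial 3-sigma band of the closed-form flag probability."""
        params = BehaviorParams(
            delta_left80_pct=20, delta_right80_pct=22,
            delta_left160_pct=18, delta_right160_pct=20,
            vhfd_attenuation=0.3, noise_sd_pct=10.0,
        )
        generator = rng(42)
        n = 800
        hits = sum(
            flag_scores(
                compute_scores(simulate_trial_set(params, "p", 60, generator))
            ).screening_positive
            for _ in range(n)
        )
        expected = flag_probability(params)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(hits / n - expected) < 3 * se

    def test_recovery_experiment_shape(self):
        frame = recovery_experiment(default_cohort_spec(seed=2), 3, seed=7)
        assert list(frame.columns) == [
            "replicate", "sensitivity", "specificity",
            "oracle_sensitivity", "oracle_specificity",
        ]
        assert len(frame) == 3
        values = frame[["sensitivity", "specificity"]].to_numpy()
        assert ((values >= 0) & (values <= 1)).all()
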