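"""Diagnostic test accuracy of a binary screen against a reference standard.

Given per-patient disease status (perimetry) and screening outcome (the
Rightward-Bias flag), this module builds the 2x2 confusion table and computes
sensitivity, specificity, predictive values at an assumed prevalence, overall
accuracy, binomial confidence intervals (Wald by default, Wilson and
Clopper-Pearson as alternatives), Fisher's exact test for 2x2 associations,
and the one-sample-proportion sample-size calculation used to plan a
screening study.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.stats import binom, norm
from statsmodels.stats.proportion import proportion_confint

logger = logging.getLogger(__name__)

TRUE_POSITIVE = "true_positive"
FALSE_POSITIVE = "false_positive"
FALSE_NEGATIVE = "false_negative"
TRUE_NEGATIVE = "true_negative"

CI_METHODS = ("wald", "wilson", "clopper-pearson")


def classify_case(disease_present: bool, screening_positive: bool) -> str:
    """Map (reference-standard disease, screening flag) to the 2x2 cell."""
    if disease_present:
        return TRUE_POSITIVE if screening_positive else FALSE_NEGATIVE
    return FALSE_POSITIVE if screening_positive else TRUE_NEGATIVE


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN counts of a screened cohort."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {value!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_diseased(self) -> int:
        return self.tp + self.fn

    @property
    def n_healthy(self) -> int:
        return self.tn + self.fp


def tabulate(cases: Sequence[tuple[bool, bool]]) -> ConfusionCounts:
    """Count classifications from ``(disease_present, screening_positive)`` pairs."""
    counts = {TRUE_POSITIVE: 0, FALSE_POSITIVE: 0, FALSE_NEGATIVE: 0, TRUE_NEGATIVE: 0}
    for disease_present, screening_positive in cases:
        if disease_present is None or screening_positive is None:
            raise ValueError("every case needs resolved disease and screening status")
        counts[classify_case(bool(disease_present), bool(screening_positive))] += 1
    return ConfusionCounts(
        tp=counts[TRUE_POSITIVE],
        fp=counts[FALSE_POSITIVE],
        fn=counts[FALSE_NEGATIVE],
        tn=counts[TRUE_NEGATIVE],
    )


@dataclass(frozen=True)
class Estimate:
    """A proportion with its two-sided 95% confidence interval."""

    value: float
    ci_low: float
    ci_high: float


def proportion_ci(
    count: int, nobs: int, method: str = "wald", alpha: float = 0.05
) -> tuple[float, float]:
    """Two-sided CI for a binomial proportion, bounds clipped to [0, 1].

    ``wald`` is the normal-approximation interval p +/- z*sqrt(p(1-p)/n);
    ``wilson`` and ``clopper-pearson`` delegate to statsmodels.
    """
    if method == "wald":
        p = count / nobs
        z = norm.ppf(1 - alpha / 2)
        half = z * math.sqrt(p * (1 - p) / nobs)
        return max(0.0, p - half), min(1.0, p + half)
    if method == "wilson":
        low, high = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    elif method == "clopper-pearson":
        low, high = proportion_confint(count, nobs, alpha=alpha, method="beta")
    else:
        raise ValueError(f"ci method must be one of {CI_METHODS}, got {method!r}")
    return max(0.0, float(low)), min(1.0, float(high))


def sensitivity(counts: ConfusionCounts, ci_method: str = "wald") -> Estimate | None:
    """TP / (TP + FN); ``None`` when the cohort has no diseased cases."""
    if counts.n_diseased == 0:
        return None
    p = counts.tp / counts.n_diseased
    return Estimate(p, *proportion_ci(counts.tp, counts.n_diseased, ci_method))


def specificity(counts: ConfusionCounts, ci_method: str = "wald") -> Estimate | None:
    """TN / (TN + FP); ``None`` when the cohort has no disease-free cases."""
    if counts.n_healthy == 0:
        return None
    p = counts.tn / counts.n_healthy
    return Estimate(p, *proportion_ci(counts.tn, counts.n_healthy, ci_method))


def predictive_values(
    sens: float, spec: float, prevalence: float = 0.5
) -> tuple[float | None, float | None]:
    """PPV and NPV at an assumed prevalence via Bayes' formulas.

    ``ppv = sens*prev / (sens*prev + (1-spec)(1-prev))`` and symmetrically for
    NPV.  A zero denominator yields ``None`` for that value.
    """
    for name, value in (("sens", sens), ("spec", spec), ("prevalence", prevalence)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    ppv_den = sens * prevalence + (1 - spec) * (1 - prevalence)
    npv_den = spec * (1 - prevalence) + (1 - sens) * prevalence
    ppv = sens * prevalence / ppv_den if ppv_den > 0 else None
    npv = spec * (1 - prevalence) / npv_den if npv_den > 0 else None
    return ppv, npv


def predictive_value_ci(
    counts: ConfusionCounts, prevalence: float = 0.5, alpha: float = 0.05
) -> tuple[tuple[float, float] | None, tuple[float, float] | None]:
    """Delta-method 95% CIs for the Bayes-formula PPV and NPV.

    Propagates the binomial sampling variance of sensitivity and specificity
    through the predictive-value formulas; bounds clipped to [0, 1].
    """
    if counts.n_diseased == 0 or counts.n_healthy == 0:
        return None, None
    se_ = counts.tp / counts.n_diseased
    sp = counts.tn / counts.n_healthy
    var_se = se_ * (1 - se_) / counts.n_diseased
    var_sp = sp * (1 - sp) / counts.n_healthy
    z = norm.ppf(1 - alpha / 2)
    q = 1 - prevalence

    out = []
    for value, d_se, d_sp in (
        (  # PPV = se*p / (se*p + (1-sp)*q)
            se_ * prevalence / (se_ * prevalence + (1 - sp) * q),
            prevalence * (1 - sp) * q / (se_ * prevalence + (1 - sp) * q) ** 2,
            se_ * prevalence * q / (se_ * prevalence + (1 - sp) * q) ** 2,
        ),
        (  # NPV = sp*q / (sp*q + (1-se)*p)
            sp * q / (sp * q + (1 - se_) * prevalence),
            sp * q * prevalence / (sp * q + (1 - se_) * prevalence) ** 2,
            (1 - se_) * prevalence * q / (sp * q + (1 - se_) * prevalence) ** 2,
        ),
    ):
        half = z * math.sqrt(d_se**2 * var_se + d_sp**2 * var_sp)
        out.append((max(0.0, value - half), min(1.0, value + half)))
    return out[0], out[1]


def overall_accuracy(counts: ConfusionCounts) -> tuple[float, float]:
    """(TP+TN)/n together with the observed prevalence (TP+FN)/n."""
    if counts.n == 0:
        raise ValueError("overall accuracy undefined for an empty cohort")
    return (counts.tp + counts.tn) / counts.n, counts.n_diseased / counts.n


@dataclass(frozen=True)
class AccuracyReport:
    """Full accuracy summary of a screened cohort."""

    counts: ConfusionCounts
    sensitivity: Estimate | None
    specificity: Estimate | None
    ppv: float | None
    npv: float | None
    ppv_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None
    overall_accuracy: float
    prevalence_assumed: float
    prevalence_observed: float
    ci_method: str


def evaluate_counts(
    counts: ConfusionCounts, prevalence: float = 0.5, ci_method: str = "wald"
) -> AccuracyReport:
    """Compute every accuracy statistic from a bare 2x2 confusion table."""
    sens = sensitivity(counts, ci_method)
    spec = specificity(counts, ci_method)
    if sens is not None and spec is not None:
        ppv, npv = predictive_values(sens.value, spec.value, prevalence)
        ppv_ci, npv_ci = predictive_value_ci(counts, prevalence)
    else:
        ppv = npv = ppv_ci = npv_ci = None
    acc, observed = overall_accuracy(counts)
    return AccuracyReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        ppv_ci=ppv_ci,
        npv_ci=npv_ci,
        overall_accuracy=acc,
        prevalence_assumed=prevalence,
        prevalence_observed=observed,
        ci_method=ci_method,
    )


def format_report(report: AccuracyReport) -> str:
    """Human-readable summary, percentages to one decimal place."""

    def pct(x: float | None) -> str:
        return "undefined" if x is None else f"{100 * x:.1f}%"

    def est(e: Estimate | None) -> str:
        if e is None:
            return "undefined"
        return f"{100 * e.value:.1f}% (95% CI {100 * e.ci_low:.1f}-{100 * e.ci_high:.1f})"

    c = report.counts
    lines = [
        f"Confusion counts: TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn} (n={c.n})",
        f"Sensitivity: {est(report.sensitivity)}",
        f"Specificity: {est(report.specificity)}",
        f"PPV (prevalence {pct(report.prevalence_assumed)}): {pct(report.ppv)}",
        f"NPV (prevalence {pct(report.prevalence_assumed)}): {pct(report.npv)}",
        f"Overall accuracy: {pct(report.overall_accuracy)}",
        f"Observed prevalence: {pct(report.prevalence_observed)}",
        f"CI method: {report.ci_method}",
    ]
    return "\n".join(lines)


# --- Fisher's exact test -----------------------------------------------------


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Enumerates the hypergeometric distribution over all tables with the
    observed margins and sums the probabilities of every table whose point
    probability does not exceed that of the observed one (the conventional
    point-probability rule).  Probabilities are compared as exact integers
    (binomial-coefficient numerators over a common denominator), so ties are
    resolved exactly rather than to floating-point tolerance.
    """
    (a, b), (c, d) = ((int(x) for x in row) for row in table)
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("table cells must be non-negative integers")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        warnings.warn("degenerate margins: Fisher exact p-value is 1", stacklevel=2)
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    numerators = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    observed = numerators[a - lo]
    total = sum(numerators)  # == comb(n, c1) by Vandermonde
    p = sum(v for v in numerators if v <= observed) / total
    return min(1.0, p)


def association_test(
    group_a: Sequence[bool], group_b: Sequence[bool]
) -> tuple[np.ndarray, float]:
    """Cross-tabulate two binary groupings over the same patients and test.

    Returns the 2x2 table ``[[a&b, a&~b], [~a&b, ~a&~b]]`` and the two-sided
    Fisher exact p-value.  An empty stratum (zero margin) still returns the
    table but the test is flagged underpowered via a warning (p = 1).
    """
    a = np.asarray(group_a, dtype=bool)
    b = np.asarray(group_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("groupings must cover the same patients")
    table = np.array(
        [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
    )
    return table, fisher_exact(table)


# --- sample size -------------------------------------------------------------


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design parameters for a one-sample proportion screening study.

    ``p0`` is the null (chance-level) proportion, ``p1`` the anticipated test
    performance, tested two-sided at ``alpha`` with the given power; the
    required number of positive cases is inflated to a total via the assumed
    disease prevalence.
    """

    p0: float = 0.5
    p1: float = 0.8
    alpha: float = 0.05
    power: float = 0.8
    assumed_prevalence: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.p0 < self.p1 < 1:
            raise ValueError(f"need 0 < p0 < p1 < 1, got p0={self.p0}, p1={self.p1}")
        if not 0 < self.assumed_prevalence <= 1:
            raise ValueError("assumed_prevalence must be in (0, 1]")


def required_sample_size(
    spec: SampleSizeSpec = SampleSizeSpec(), method: str = "normal"
) -> tuple[int, int]:
    """Minimum positive cases and total cohort size for the screening design.

    ``normal`` uses the two-sided normal-approximation formula
    ``n = ((z_{a/2} sqrt(p0 q0) + z_b sqrt(p1 q1)) / (p1 - p0))^2`` rounded up;
    ``exact`` searches for the smallest n whose exact binomial test (upper
    critical region at alpha/2) reaches the requested power under p1.
    """
    if method == "normal":
        z_alpha = norm.ppf(1 - spec.alpha / 2)
        z_beta = norm.ppf(spec.power)
        numerator = z_alpha * math.sqrt(spec.p0 * (1 - spec.p0)) + z_beta * math.sqrt(
            spec.p1 * (1 - spec.p1)
        )
        n_positive = math.ceil((numerator / (spec.p1 - spec.p0)) ** 2)
    elif method == "exact":
        n_positive = None
        for n in range(2, 10_000):
            # smallest k with P(X >= k | p0) <= alpha/2
            k = int(binom.isf(spec.alpha / 2, n, spec.p0)) + 1
            if binom.sf(k - 1, n, spec.p0) > spec.alpha / 2:
                k += 1
            if binom.sf(k - 1, n, spec.p1) >= spec.power:
                n_positive = n
                break
        if n_positive is None:  # pragma: no cover - unreachable for sane specs
            raise RuntimeError("exact sample-size search did not converge")
    else:
        raise ValueError(f"method must be 'normal' or 'exact', got {method!r}")
    n_total = math.ceil(n_positive / spec.assumed_prevalence)
    logger.debug("sample size (%s): %d positives, %d total", method, n_positive, n_total)
    return n_positive, n_total
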