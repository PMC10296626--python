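# Methods

## Scoring model

A BRIT protocol is 30 signed bisection deviations: 5 trials × {80, 160} mm ×
{plain, left-expansion, right-expansion}. Deviations are integer millimetres
(rightward positive); fractional input is rejected rather than silently
rounded, with `round_deviation` (halves away from zero) provided for the
examiner. A mark cannot fall outside the line, so |deviation| ≤ half-length.

Per condition a central tendency is taken — the arithmetic mean by default
(the published scoring rule), or the median (3rd order statistic of 5, no
interpolation) as the outlier-robust variant. The five indexes are

- `LB80`, `LB160`: the plain-line centers, reported in mm and as percent of
  the half-length (`pct = mm / (L/2) × 100`, exactly invertible);
- `SIE_L = [left-expansion − plain] + [right-expansion − plain]` per length;
- `LE = LB160% − LB80%`.

**Age adjustment.** The normative scoring pipeline this package mirrors
applies an age adjustment whose coefficients live in the instrument's
normative spreadsheet, not in any formula we can cite. The package therefore
exposes a pluggable `NormativeAdjustment` callable
(`(value_pct, age, index) -> adjusted_pct`); the default is the identity,
clearly labelled via `BritScores.age_adjusted`. Every accuracy quantity the
package reports is computed from counts and percentages that do not depend
on this choice. With the identity adjustment `LE` equals `LB160% − LB80%`
exactly (with a non-trivial adjustment it is approximate, which is why the
instrument's documentation marks it "approx.").

**Cut-offs and flags.** SIE rightward cut-offs: 7.8 mm = 19.5 % (short),
11.8 mm = 14.75 % (long); the mm/percent pair is validated for consistency.
"Exceeds the cut-off" is strict (`>`) for SIE and LE; LB cut-offs
(+8.50 % / +12.25 %) are published as "≥" and applied inclusively. LE flags
high bias above +6.7 % and low bias below −6.5 %. The *leftward* SIE cut-off
magnitude is not published; by default it mirrors the rightward cut-off
(`sie_left_mirror=True`), and explicit values can be injected — an assumption
documented here because leftward flags only feed a subsidiary association
test, never the screening decision. `screening_positive` is true iff either
SIE flags a Rightward Bias (one line suffices).

**Variability.** Per-condition CoV = sample SD (ddof = 1) / |mean| of the 5
trials; a zero mean makes CoV *undefined* (reported as `None`), never an
infinity; CoV > 0.50 is flagged as high variability.

## Neglect classification and groups

The standard battery comprises eleven tests with published cut-offs
(cancellation and asymmetry scores fail high; Apples accuracy ≤ 44 and
sentence reading ≤ 5 fail low; plain-line bisection fails above 6.73 %).
Neglect (N+) requires failing at least two tests. Groups combine this label
with the perimetry reference standard (absent / hemianopia / superior or
inferior quadrantanopia): N+H+, N+H−, N−. Patients with missing battery or
perimetry are scored but excluded from accuracy analyses; partially completed
trial sets are rejected outright (the 5 × 6 structure is an invariant, and no
principled imputation exists for a 5-trial condition).

## Diagnostic accuracy

Classification against perimetry follows the standard 2×2 mapping
(disease × Rightward Bias). Accuracy evaluation restricts to N+ patients by
default: the screen answers "does this *neglect* patient also have a field
deficit", and patients without neglect enter the study only as a
no-false-positive check. Sensitivity, specificity and overall accuracy are
the usual count ratios; PPV/NPV are computed at an assumed prevalence
(default 50 %, the literature prevalence of VHFD in neglect) via Bayes'
formulas, which at the observed prevalence reduce to the raw column
proportions.

**Confidence intervals.** The default is the Wald normal-approximation
interval `p ± 1.96·√(p(1−p)/n)` clipped to [0, 1] — the method that
reproduces the instrument study's printed intervals. Wilson and
Clopper–Pearson are available (via statsmodels) for users who prefer
boundary-respecting intervals at these small n; delta-method intervals are
provided for PPV/NPV.

**Fisher's exact test** is implemented by hypergeometric enumeration with
exact integer arithmetic: table weights are binomial-coefficient numerators
over the common denominator, and the two-sided p-value sums all tables whose
weight does not exceed the observed one (the conventional point-probability
rule). Integer comparison makes tie handling exact, with no floating-point
tolerance; the test suite verifies exhaustive agreement with an independent
enumeration for every 2×2 table with total ≤ 40 and with scipy on random
tables. Degenerate margins return p = 1 with a warning.

**Sample size** uses the two-sided one-sample-proportion normal
approximation `n = ((z_{α/2}√(p₀q₀) + z_β√(p₁q₁))/(p₁−p₀))²` rounded up
(for p₀ = 0.5, p₁ = 0.8, α = 0.05, power = 0.8: 19.3 → 20 positive cases,
40 patients at 50 % prevalence); an exact-binomial search is offered as an
alternative.

## Synthetic cohort generator

No patient-level BRIT data are deposited, so the generator is first-class:
it emulates the study conditions, and everything downstream is validated
against it.

**Model.** Per trial,
`deviation_mm = round((bias(L) + shift(config))/100 × L/2 + ε)`, clipped to
the line, with `shift = 0` (plain), `−a·δ_left(L)` (left expansion),
`+δ_right(L)` (right expansion) and `ε ~ N(0, σ·L/200)`. The attenuation `a`
encodes the perimetry outcome: 1 for an intact field, 0 for hemianopia
(left illusion fully suppressed), 0.5 for quadrantanopia — a partial-
suppression assumption consistent with quadrantanopias being detected less
reliably, and tunable per group. Rounding to integer mm happens after noise,
matching the measurement convention. This additive bias + shift + noise
structure is the minimal model consistent with the instrument's rationale
and the SIE formula; the noise-free SIE is exactly
`δ_right − a·δ_left` (in %), independent of the neutral bias.

**Illusion shifts are per line length** (δ_left/δ_right for 80 and 160 mm
separately): empirically the illusory effect in percent is larger on the
short line, and a single shared pair cannot reproduce both group anchors.

**Calibration.** Default group priors (Gaussian, clipped at natural bounds)
are set so simulated score means/SDs approximate the study's group summaries
— e.g. N+H+ SIE80 ≈ +28.7 % (SD ≈ 21), N+H− ≈ −1.6 % (14), N− ≈ −2.5 %
(5.2), LB160 ≈ +24.5 % in N+H+ — with group sizes 23/22/19 and the 18:4:1
hemianopia:inferior:superior mix among N+H+. Trial noise (σ ≈ 12 % of the
half-length for neglect groups, 4 % for N−) is chosen to jointly satisfy the
score-level SDs and the high trial-to-trial variability of neglect
performance (mean per-condition CoV > 0.5 for at least 5 of 6 conditions,
with the long right-expansion line the natural exception — its condition
mean is furthest from zero). Score summaries alone do not identify
trial-level noise, so this split of between-patient vs within-patient
variance is a modelling choice; both pieces are tunable. Battery scores are
drawn from group-level priors and minimally edited when a draw would
contradict the group's neglect label.

**What the generator does not emulate:** response omissions and partial
protocols, heavy-tailed or sequentially dependent responses (a contamination
option exists for mean-vs-median experiments), age effects on performance,
and any lesion-anatomy structure. Passing tests therefore demonstrate that
the pipeline is correct under the stated generative model, not that the
instrument achieves the same accuracy in new clinical samples.

**Closed-form oracle.** Under the model, each SIE percentage is Gaussian
with mean `δ_right − a·δ_left` and variance `6σ²/5` (three condition
centers, weights 1, 1, −2, each a mean of 5 trials) plus a millimetre-
quantization term `(6/60)·(100/(L/2))²` from treating per-trial rounding as
uniform on ±0.5 mm; the two lengths use disjoint trials, so
`P(positive) = 1 − Φ₈₀·Φ₁₆₀`. Clipping at the line ends is ignored
(negligible at realistic parameters). `recovery_experiment` compares
Monte-Carlo sensitivity/specificity with the mean per-patient oracle
probability; with 500 replicates of the default 64-patient cohort the paired
difference sits well within 3 Monte-Carlo standard errors. Common random
numbers across attenuation levels are obtained for free because attenuation
enters deterministically given the drawn perimetry outcome, leaving the
random stream untouched.

## Numerical and design choices

- Deterministic outputs: all randomness flows through a single
  `numpy.random.Generator` seeded per cohort; identical config + seed gives
  byte-identical pipeline outputs.
- Reported percentages are rounded to one decimal in the human-readable
  summary; machine-readable CSV/JSON retain full precision.
- Problem sizes in the test suite (exhaustive Fisher check to total 40,
  500-replicate recovery runs, 8-cohort calibration pools) were chosen as
  the smallest sizes at which the checks are statistically meaningful.
- The CLI is a thin argparse layer; every subcommand is a few library calls,
  and a `key=value` config file can preset cut-offs and analysis choices.

## Known limitations

- The identity default for age adjustment means raw and "adjusted" scores
  coincide unless the user injects normative coefficients.
- The published specificity interval appears in two inconsistent versions in
  the source material (75.2–100.0 vs 78.9–100.0); the Wald interval
  reproduces the latter, and no attempt is made to reverse-engineer the
  former.
- PPV/NPV interval methodology for the original figures is unstated; the
  delta-method intervals here are a reasonable default, not a reproduction.
- The Gaussian noise model understates the heavy-tailed outliers real
  neglect patients produce; the contamination option only partially covers
  this.
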