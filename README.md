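# britscreen

Scoring, screening and diagnostic-accuracy analysis for the **Brentano
Illusion Test (BRIT)** — a paper-and-pencil line-bisection instrument used to
screen for **left visual hemi-field deficits (VHFD)**, such as hemianopia or
quadrantanopia, in stroke patients with right-brain damage and unilateral
spatial neglect.

## Who this is for

Clinical neuropsychologists assess neglect at the bedside, but a co-occurring
visual field loss often goes undiagnosed until a formal perimetry (the
Humphrey Field Analyzer, the reference standard) becomes available. The BRIT
exploits an asymmetry: neglect patients with an intact visual field perceive
the Brentano (double Mueller-Lyer) illusion on both sides of a bisected line,
whereas patients with a left VHFD fail to perceive the left-side illusion of
length expansion and therefore bisect far to the right of it. This package
implements the complete quantitative workflow around that idea: validated
data containers and CSV I/O, index scoring and cut-off flags, screening
accuracy against the perimetry reference standard, and a calibrated synthetic
cohort generator so the whole pipeline is testable without patient data.

## The model in brief

Each patient bisects 30 lines: 5 trials for each of 6 conditions (80 and
160 mm lines; plain, left-expansion, right-expansion). Signed deviations from
the true midpoint (mm, rightward positive) yield five indexes:

- `LB80`, `LB160` — mean deviation on the plain lines, also as a percent of
  the half-length;
- `LE = LB160% − LB80%` — the Length Effect;
- per length, the **Symmetry of the Illusory Effect**

  `SIE = [left-expansion − plain] + [right-expansion − plain]`.

A symmetric responder has SIE ≈ 0; a suppressed left illusion leaves only the
rightward term. A **Rightward Bias** — SIE exceeding 7.8 mm (19.5 %) on the
short line or 11.8 mm (14.75 %) on the long line, on either line or both —
is the screening-positive signal. Screened patients are tabulated against
perimetry as TP/FP/FN/TN, giving sensitivity, specificity, PPV/NPV at an
assumed 50 % prevalence (Bayes' formulas), overall accuracy, Wald 95 %
confidence intervals, and Fisher exact tests for the subsidiary questions.

The synthetic generator draws per-patient parameters (baseline rightward
bias, illusion shift magnitudes, a left-illusion attenuation tied to the
perimetry outcome, trial noise) and produces integer-mm trials via

`deviation = round((bias + shift)/100 × half_length + ε)`, `ε ~ N(0, σ)`.

See `docs/methods.md` for assumptions, calibration and limitations.

## Worked example

Evaluate a screening study directly from its confusion counts (TP FP FN TN):

```sh
$ britscreen evaluate --counts 18 2 5 20
Confusion counts: TP=18 FP=2 FN=5 TN=20 (n=45)
Sensitivity: 78.3% (95% CI 61.4-95.1)
Specificity: 90.9% (95% CI 78.9-100.0)
PPV (prevalence 50.0%): 89.6%
NPV (prevalence 50.0%): 80.7%
Overall accuracy: 84.4%
Observed prevalence: 51.1%
CI method: wald
```

Of 23 patients with a perimetry-confirmed VHFD, 18 showed a Rightward Bias
(sensitivity 78.3 %); of 22 without, 20 were correctly negative (specificity
90.9 %). At 50 % prevalence, a positive screen implies an 89.6 % probability
of a true field deficit — such patients are referred urgently for formal
perimetry, negatives non-urgently.

The same numbers fall out of a full patient-level run on a simulated cohort:

```sh
britscreen simulate --output cohort --seed 7
britscreen evaluate --trials cohort/trials.csv --metadata cohort/metadata.csv
```

and the design question "how many patients does such a screening study need"
is answered by

```sh
$ britscreen samplesize --p0 0.5 --p1 0.8 --power 0.8
minimum positive cases: 20
minimum total cohort (prevalence 50%): 40
```

From Python, the same pipeline is three calls:

```python
from britscreen import default_cohort_spec, simulate_cohort, screening_outcomes
cohort = simulate_cohort(default_cohort_spec(seed=7))
outcomes = screening_outcomes(cohort)   # per-patient flags + oracle probabilities
```

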