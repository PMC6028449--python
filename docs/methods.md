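# Methods

## The screening instrument as a rule engine

The CDEPA checklist is represented as data (`src/cdepa/data/cdepa_default.yaml`):
19 yes/no symptoms, each with a stable id, an area (one of six: general
characteristics, disability, treatment-related motor, disease-related
motor, disease-related non-motor, neuropsychiatric/cognitive) and a
certainty tier (definitive / probable / possible). Five symptoms are
definitive: severe disability requiring help for ADL, motor fluctuations
with off time >25% limiting basic ADL, severe dysphagia, recurrent falls,
dementia.

Case-level certainty is the maximum over the fired clauses:

| clause | condition | case level |
|---|---|---|
| definitive symptom | ≥ 1 definitive "yes" | definitive |
| probable cross-area promotion | probable "yes" symptoms span ≥ 2 distinct areas | definitive |
| probable symptom | ≥ 1 probable "yes" | probable |
| possible pair promotion | possible "yes" in a disease-related area **and** in the neuropsychiatric/cognitive area | probable |
| possible symptom | ≥ 1 possible "yes" | possible |

Design choices where the instrument's published layout is open:

* **Single-pass evaluation.** Promotions read *symptom-level* tiers only;
  a case promoted to probable by the possible-pair clause does not count
  as a "probable symptom" for the cross-area clause. No fixed-point
  iteration.
* **Binary screen threshold.** Only case level = definitive screens
  positive for APD (this is the instrument's own reading); the threshold
  is configurable to probable for sensitivity analyses.
* **Ambiguous tiers.** For five symptoms (symptomatic dysautonomia,
  excessive daytime somnolence, moderate–severe apathy, psychotic
  symptoms, mild cognitive impairment) the published flattened layout
  does not pin the tier unambiguously; the packaged YAML flags these rows
  with comments so users can amend them without code changes.
* **Missing answers** are coerced to "no" with a warning by default
  (symptom *presence* requires an explicit "yes"); a strict mode turns
  them into errors. Off/on-time >25% items are taken as already
  adjudicated yes/no; no diary arithmetic is performed.

The engine is monotone by construction (flipping any answer no→yes can
only add fired clauses), which the tests verify by enumeration, and it is
checked exhaustively against an independent transcription of the clause
definitions on a reduced 8-symptom taxonomy (2^8 patterns).

## Scale scoring

* **SCOPA-Motor (S-MS).** Sections are scored as sums of 0–3 items with
  section ranges 0–42 (examination), 0–21 (ADL), 0–6 + 0–6
  (dyskinesias/fluctuations; complications 0–12), total 0–75. The stated
  section ranges fix the per-section item counts used here
  (14/7/2/2, in `SMS_SECTION_ITEMS`); the scale literature's "21 items"
  does not reconcile with those ranges at 0–3 per item, and the ranges
  are treated as binding. The counts are data, not code.
* **NMSS.** 30 items, item score = severity (0–3) × frequency (1–4),
  domain partition 2/4/6/3/3/3/3/2/4 (cardiovascular, sleep/fatigue,
  mood/cognition, perceptual/hallucinations, attention/memory,
  gastrointestinal, urinary, sexual, miscellaneous), total 0–360.
* **CISI-PD.** Four clinician items 0–6, total 0–24. **CGIS** 1–7,
  **PGIS** 1–6. **Hoehn–Yahr** integer 1–5 only; half-stages of the
  modified scale are rejected because the validation design used integer
  stages.
* **Gold standard.** The neurologist's five-level clinical stage
  (initial / mild / moderate / advanced / late-stage) binarizes as
  advanced ⇔ {advanced, late-stage}.
* **Missing items** are never imputed: an instrument with any missing
  item scores null (NaN in tabular outputs) and is flagged incomplete.

## Validation statistics — numerical choices

* Performance ratios are undefined (not 0) on zero margins; the report
  carries a message per undefined entry. Binary AUC is defined as
  (Se + Sp)/2 — the area under the single-operating-point ROC polygon —
  because the index test is dichotomous; no rank-based AUC is computed.
* Cohen's κ uses the Fleiss–Cohen–Everitt large-sample variance for the
  SE/CI (CI truncated to [−1, 1]) and the null-variance formula for the
  significance test; both are cross-checked against statsmodels in the
  tests. Landis–Koch bands are applied to κ rounded to two decimals;
  negative κ is labelled "below negligible".
* Printed-style renderings round half away from zero (percentages to one
  decimal, κ to two); stored values keep full precision so rounding never
  contaminates downstream numbers.
* Mann–Whitney U uses the exact permutation null when min(n₁, n₂) ≤ 8 and
  there are no ties, otherwise the tie-corrected normal approximation
  with continuity correction. Spearman ρ uses mid-ranks; Kruskal–Wallis
  applies the tie correction and returns H = 0, p = 1 for all-equal data.
  These standard tests are computed via scipy behind the package surface;
  the tests compare them against brute-force enumerations.
* The Youden cutoff evaluates "positive if score ≥ c" at every observed
  score, maximizes J = Se + Sp − 1, and breaks ties toward the smallest
  cutoff; the full per-cutoff table is returned. Constant scores yield a
  degenerate result with a warning.
* Power of the two-sided one-sample proportion test: rejection boundaries
  p₀ ± z₍₁₋α/₂₎·√(p₀q₀/n); power is the probability mass beyond either
  boundary with the sampling SD evaluated at p₁; no continuity
  correction. At p₀ = 0.25, p₁ = 0.40, n = 100, α = 0.05 this gives 0.91,
  matching an exact-binomial Monte-Carlo rejection rate within ±0.02.

## The synthetic cohort

No patient-level data accompany the validation study, so the simulator
generates cohorts with the structure the analysis assumes. Per patient:

1. **HY stage** ~ categorical(0.094, 0.333, 0.298, 0.222, 0.053) — the
   study's stage distribution.
2. **Latent severity** s = HY + U(−0.5, 0.5). This continuum is a working
   construct of the generator, not a measured quantity.
3. **Gold-standard stage** from a noisy threshold model: stage cutpoints
   applied to s + σε, ε ~ N(0, 1), σ = 0.70. The noise width sets how
   strongly the clinician's stage tracks HY (Spearman ρ ≈ 0.785 at the
   default); cutpoints were chosen as quantiles giving stage fractions
   0.11 / 0.26 / 0.254 / 0.306 / 0.07, hence 37.6% gold-advanced.
4. **Symptom answers**: yes with probability logistic(b·(s − m)) per
   symptom, independent given s.
5. **Scale scores** drawn from group-conditional normals — conditioning
   on the patient's *CDEPA screen result*, which is how the study
   tabulates them — clipped to the instrument range and rounded to
   integers. Clipping (rather than renormalized truncation) leaves tail
   behaviour above the cutoff region unchanged. CGIS/PGIS group
   parameters are not reported anywhere and are extrapolated synthetic
   working values (flagged in the YAML).
6. **Demographics**: age ~ N(68.4, 10.5²) clipped to [30, 95], 40.4%
   women, disease duration ~ N(10.3, 5.8²) floored at the 2-year
   inclusion criterion.
7. **Second rater / retest**: each answer independently flipped with
   probability 0.018 / 0.026.

### Calibration

Stage-noise σ, cutpoints, shared shifts/scales of the symptom logistic
models, and the flip probabilities are free parameters calibrated once
(`scripts/calibrate.py`) and frozen into the packaged YAML. The symptom
search optimizes a closed-form P(screen positive | s) — exact given the
conditional-independence structure — over 200,000 Monte-Carlo severity
draws, targeting the study's margins: P(CDEPA+) = 0.630,
P(CDEPA+ | gold+) = 0.969, P(CDEPA+ | gold−) = 0.426. Slope scales are
penalized outside [0.7, 1.5]: the unconstrained optimum drives the
definitive-tier slopes toward near-step functions, which is clinically
implausible and makes the logistic slopes unidentifiable. The constrained
fit achieves P(CDEPA+) = 0.632, sensitivity 0.957, false-positive rate
0.437; all confusion-matrix cell proportions are within 0.01 of the
study's. At n = 10,000 the default configuration gives gold-advanced
≈ 0.37, CDEPA-advanced ≈ 0.62–0.63, stage–HY ρ ≈ 0.79, inter-rater
diagnosis κ ≈ 0.89, and test–retest κ ≈ 0.85.

### What the generator does not emulate

* Joint correlation among scale scores beyond the shared latent severity
  and screen-group conditioning (no covariance information is reported).
* Longitudinal progression; cohorts are single-visit cross-sections.
* Real response-pattern structure: symptoms are conditionally
  independent given severity, so multi-symptom co-occurrence is
  understated relative to clinical reality.

Passing calibration tests therefore show that the *pipeline* behaves
correctly under the study's marginal structure — not that the generator
reproduces real patients.

### A note on the CISI-PD cutoff

For the reported group distributions (advanced 13.0 ± 4.0, non-advanced
5.1 ± 3.2), the population Youden optimum lies almost exactly at 9.0, so
integer cutoffs 9 and 10 are near-tied (exact tail computation:
J(9) = 0.7257 vs J(10) = 0.7246). Finite cohorts of 109/64 therefore
return 9 or 10 with nearly equal frequency; the *modal* cutoff over
repeated simulation is the stable summary and is what the tests and the
acceptance script report.

## Problem sizes

Calibration checks run at n = 10,000 simulated patients; parameter
recovery (per-symptom logistic refits) at n = 5,000; cutoff recovery over
50 cohorts of the study's 109/64 group sizes; rule-engine equivalence
over all 2^8 patterns of the reduced taxonomy plus 10,000 random
monotonicity probes. The full suite runs in a few seconds on one CPU.

## Known limitations

* The κ confidence interval uses the asymptotic SE; no bootstrap or exact
  interval is offered (the study reports none to compare against).
* No multi-rater (> 2) or weighted κ; the design is two-rater binary.
* Wilson intervals for sensitivity/specificity are not implemented.
* The S-MS per-item composition is a best reconstruction from the stated
  section ranges; correct it in `SMS_SECTION_ITEMS` against the original
  instrument if needed.
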