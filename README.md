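# cdepa

Rule engine and validation-statistics pipeline for the **CDEPA**
questionnaire ("Cuestionario De Enfermedad de Parkinson Avanzada"), a
neurologist-administered screening instrument for **advanced Parkinson's
disease (APD)**.

## What this package is for

Deciding when Parkinson's disease has become *advanced* matters clinically:
advanced patients respond poorly to conventional therapy and become
candidates for device-aided treatments. The CDEPA instrument screens for
APD with a yes/no symptom checklist in which every symptom carries a
certainty tier — *definitive*, *probable*, or *possible* — within one of
six symptom areas. Case-level certainty follows three combination rules:

* any **definitive** symptom (severe disability requiring help for ADL,
  motor fluctuations with off time >25% limiting basic ADL, severe
  dysphagia, recurrent falls, or dementia) makes the case definitive —
  i.e. screens positive for APD;
* two **probable** symptoms from *different* areas promote the case to
  definitive;
* a **possible** disease-related symptom (motor or non-motor) together
  with a **possible** neuropsychiatric/cognitive symptom promotes the case
  to probable.

The package provides, for biostatisticians and movement-disorder
researchers:

* `cdepa.rules` — the checklist as editable YAML data plus a deterministic
  rule engine (`classify_case`, `classify_cohort`);
* `cdepa.scales` — scoring and range validation for the accompanying
  instruments (Hoehn–Yahr, SCOPA-Motor, NMSS, CISI-PD, CGIS/PGIS) and the
  five-level gold-standard clinical stage with its advanced/non-advanced
  binarization;
* `cdepa.stats` — the validation statistics: 2×2 diagnostic performance
  (sensitivity, specificity, PPV/NPV, accuracy, error rates, binary AUC
  = (Se + Sp)/2), Cohen's κ = (p_o − p_e)/(1 − p_e) with the
  Fleiss–Cohen–Everitt standard error and Landis–Koch interpretation
  bands, percent agreement, Spearman ρ, Mann–Whitney U (exact for small
  samples), Kruskal–Wallis, Fisher's exact test, Youden-index
  (J = Se + Sp − 1) cutoff search, and the normal-approximation power of
  a one-sample proportion test;
* `cdepa.simulate` — a seeded synthetic-cohort generator calibrated so
  that simulated cohorts reproduce the validation study's marginal
  structure (no patient-level data are distributed with the study);
* `cdepa.pipeline` / the `cdepa` CLI — end-to-end orchestration with JSON
  reports.

## Worked example

Feed the validation study's 2×2 classification counts (index test =
CDEPA, reference = neurologist's clinical judgment) straight into the
statistics engine:

```bash
cdepa stats --table 63,46,2,62
```

```json
{
  "counts": {"tp": 63, "fp": 46, "fn": 2, "tn": 62, "n": 173},
  "performance_pct": {
    "sensitivity": 96.9, "specificity": 57.4, "ppv": 57.8, "npv": 96.9,
    "accuracy": 72.3, "fp_rate": 42.6, "fn_rate": 3.1, "auc_binary": 77.2
  },
  "kappa": 0.48,
  "kappa_label": "moderate"
}
```

Reading: of 65 truly advanced patients the questionnaire catches 63
(sensitivity 96.9%) and misses 2 (3.1%); of 108 non-advanced patients it
over-calls 46 (specificity 57.4%), so a positive screen is right 57.8% of
the time while a negative screen is right 96.9% of the time — the profile
of a deliberately sensitive screening instrument. Chance-corrected
agreement with the clinical gold standard is moderate (κ = 0.48).

The same analysis run end to end on a fresh synthetic cohort of 173
patients (simulate → classify → validate, including second-rater and
retest passes):

```bash
cdepa replicate --seed 1 --n 173 --out report.json
```

```text
n = 173 (tp 64, fp 43, fn 1, tn 65)
Sensitivity was 98.5%; specificity was 60.2%; false positives were 39.8%; false negatives were 1.5%; positive predictive value was 59.8%; negative predictive value was 98.5%; total accuracy was 74.6%
Binary-classifier AUC: 79.3%
Cohen's kappa vs gold standard: 0.52 (moderate, p = 1.5e-14)
Inter-rater: agreement 94.8%, kappa 0.89 (almost perfect)
Test-retest: agreement 90.2%, kappa 0.78 (substantial)
```

Other subcommands: `cdepa simulate` (write responses/scales/truth CSVs),
`cdepa classify` (rule engine only), `cdepa validate` (analysis on your
own CSVs). See `docs/methods.md` for the model and its assumptions.

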