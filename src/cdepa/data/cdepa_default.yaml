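# Default CDEPA rule map: symptom checklist with certainty tiers and areas.
#
# The five definitive symptoms (any one of which screens the patient as
# advanced PD) are: severe disability requiring help for ADL, motor
# fluctuations with off time >25% limiting basic ADL, severe dysphagia,
# recurrent falls, and dementia.
#
# NOTE on tier assignments: the published layout of the checklist is
# ambiguous for a few rows.  The tiers below for symptomatic dysautonomia,
# excessive daytime somnolence, moderate-severe apathy, psychotic symptoms,
# and mild cognitive impairment follow the most consistent reading of the
# instrument (possible unless listed among the definitive symptoms or the
# clearly probable ones); amend here — not in code — if your copy of the
# instrument differs.
#
# Off-time / on-time >25% items are adjudicated yes/no by the clinician;
# the engine does not compute diary percentages.

symptoms:
  - id: evolution_10y
    label: "Evolution time around 10 years"
    area: general_characteristics
    level: probable

  - id: adl_requiring_help
    label: "Severe disability: requiring help to perform daily living activities"
    area: disability
    level: definitive
  - id: adl_limitation_no_help
    label: "Limitation to perform basic activities, although not requiring help"
    area: disability
    level: probable

  - id: fluctuations_off_gt25
    label: "Motor fluctuations with an off time >25%, with limitation to perform basic activities without requiring help"
    area: treatment_motor
    level: definitive
  - id: dyskinesia_on_gt25
    label: "Functional disability due to dyskinesias with an on time >25%"
    area: treatment_motor
    level: probable

  - id: severe_dysphagia
    label: "Severe dysphagia"
    area: disease_motor
    level: definitive
  - id: recurrent_falls
    label: "Recurrent falls"
    area: disease_motor
    level: definitive
  - id: moderate_dysphagia
    label: "Moderate dysphagia"
    area: disease_motor
    level: probable
  - id: freezing_of_gait
    label: "Freezing of gait"
    area: disease_motor
    level: probable
  - id: dysarthria_moderate_severe
    label: "Moderate-severe dysarthria"
    area: disease_motor
    level: possible
  - id: postural_equilibrium_disorders
    label: "Postural and equilibrium disorders"
    area: disease_motor
    level: possible

  - id: symptomatic_dysautonomia    # tier ambiguous in source layout; see header note
    label: "Symptomatic dysautonomia, including orthostatic symptomatic hypotension"
    area: disease_non_motor
    level: possible
  - id: daytime_somnolence          # tier ambiguous in source layout; see header note
    label: "Excessive daytime somnolence"
    area: disease_non_motor
    level: possible

  - id: dementia
    label: "Dementia"
    area: neuropsychiatric_cognitive
    level: definitive
  - id: hallucinations_no_insight
    label: "Hallucinations without preserved insight"
    area: neuropsychiatric_cognitive
    level: probable
  - id: apathy_moderate_severe      # tier ambiguous in source layout; see header note
    label: "Moderate-severe apathy"
    area: neuropsychiatric_cognitive
    level: probable
  - id: hallucinations_with_insight
    label: "Chronic presence of hallucinations with preserved insight"
    area: neuropsychiatric_cognitive
    level: possible
  - id: psychotic_symptoms          # tier ambiguous in source layout; see header note
    label: "Psychotic symptoms"
    area: neuropsychiatric_cognitive
    level: possible
  - id: mild_cognitive_impairment   # tier ambiguous in source layout; see header note
    label: "Mild cognitive impairment"
    area: neuropsychiatric_cognitive
    level: possible

promotion_b_min_areas: 2
diagnosis_threshold: definitive
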