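# Registry of the eight brain-size regression models.
# Every model regresses log endocranial volume on log body mass plus the
# hypothesis-specific predictors; categorical baselines are set explicitly.
response: log_ecv
reference_levels:
  activity_period: nocturnal
  origin: Australia
  status: least_concern
  torpor: "no"
  play: absent
  group_living: solitary
  parental_care: minimal
  mating_system: polygynous
  shelter_safety: closed
  terrestriality: terrestrial
  diet: insectivorous
models:
  - name: developmental
    fixed: [log_body, litter_size, weaning_age]
  - name: environmental
    fixed: [log_body, activity_period, shelter_safety, terrestriality, diet, home_range]
  - name: social
    fixed: [log_body, group_living, parental_care, mating_system, population_density]
  - name: metabolic
    fixed: [log_body, fmr, "fmr:log_body"]
  - name: torpor
    fixed: [log_body, torpor, "torpor:log_body"]
  - name: play
    fixed: [log_body, play, "play:log_body"]
  - name: vulnerability
    fixed: [log_body, status, "status:log_body"]
  - name: origin
    fixed: [log_body, origin]
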