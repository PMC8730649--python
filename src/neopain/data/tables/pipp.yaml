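# Default PIPP scoring table.
#
# PROVENANCE: these breakpoints are NOT an original calibration of this
# package; they follow the published PIPP instrument (Stevens B, Johnston C,
# Petryshen P, Taddio A. Premature Infant Pain Profile: development and
# initial validation. Clin J Pain 1996;12:13-22). Facial indicators are
# scored by percent of epoch time present; physiological indicators by
# change from baseline. Edit this file for study-specific calibrations.
#
# Bin semantics: value v falls in bin i when edges[i] <= v < edges[i+1];
# the top bin is closed at the domain maximum. scores[i] is the subscore
# for bin i.
table_id: pipp-default
measure: PIPP
conditional_contextual: false
indicators:
  brow_bulge:
    kind: numeric
    domain: [0.0, 1.0]
    edges: [0.0, 0.10, 0.40, 0.70, 1.0]
    scores: [0, 1, 2, 3]
  eye_squeeze:
    kind: numeric
    domain: [0.0, 1.0]
    edges: [0.0, 0.10, 0.40, 0.70, 1.0]
    scores: [0, 1, 2, 3]
  nasolabial_furrow:
    kind: numeric
    domain: [0.0, 1.0]
    edges: [0.0, 0.10, 0.40, 0.70, 1.0]
    scores: [0, 1, 2, 3]
  heart_rate:
    # max increase from baseline, beats per minute
    kind: numeric
    domain: [0.0, .inf]
    edges: [0.0, 5.0, 15.0, 25.0, .inf]
    scores: [0, 1, 2, 3]
  oxygen_saturation:
    # max decrease from baseline, percentage points
    kind: numeric
    domain: [0.0, .inf]
    edges: [0.0, 2.5, 5.0, 7.5, .inf]
    scores: [0, 1, 2, 3]
  gestational_age:
    # corrected gestational age, completed weeks; lower GA -> higher score
    kind: numeric
    domain: [20.0, 60.0]
    edges: [20.0, 28.0, 32.0, 36.0, 60.0]
    scores: [3, 2, 1, 0]
  behavioral_state:
    kind: categorical
    categories:
      active_awake: 0
      quiet_awake: 1
      active_sleep: 2
      quiet_sleep: 3
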