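# Default PIPP-R scoring table.
#
# PROVENANCE: these breakpoints are NOT an original calibration of this
# package; they follow the published PIPP-Revised instrument (Stevens BJ,
# Gibbins S, Yamada J, et al. The Premature Infant Pain Profile-Revised
# (PIPP-R): initial validation and feasibility. Clin J Pain 2014;30:238-43).
# The PIPP-R's structural change is conditional contextual scoring: the
# gestational-age and behavioral-state subscores are added to the total only
# when the facial + physiological subtotal is greater than zero.
#
# Bin semantics: value v falls in bin i when edges[i] <= v < edges[i+1];
# the top bin is closed at the domain maximum. scores[i] is the subscore
# for bin i.
table_id: pipp-r-default
measure: PIPP-R
conditional_contextual: true
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
    kind: numeric
    domain: [0.0, .inf]
    edges: [0.0, 5.0, 15.0, 25.0, .inf]
    scores: [0, 1, 2, 3]
  oxygen_saturation:
    kind: numeric
    domain: [0.0, .inf]
    edges: [0.0, 2.5, 5.0, 7.5, .inf]
    scores: [0, 1, 2, 3]
  gestational_age:
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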