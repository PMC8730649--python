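# Four-phase heel-stick protocol: two resting baselines, then the stick
# and recovery. 30-s epochs; PIPP scoring.
schema_version: 1
template_id: expert
measure: PIPP
phases:
  - {name: baseline1, n_epochs: 2, epoch_length_s: 30.0}
  - {name: baseline2, n_epochs: 2, epoch_length_s: 30.0}
  - {name: stick, n_epochs: 4, epoch_length_s: 30.0}
  - {name: recovery, n_epochs: 4, epoch_length_s: 30.0}
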