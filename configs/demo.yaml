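# Demo configuration for `stressmeth run-all`: simulates the default study
# (22 samples, 2,000 probes, 10 planted clusters) and runs every stage.
simulate: true
alpha: 0.05
de_p: 0.05
mqtl_distance: 200
halfwidth: 250
reps: 10000
max_failed_samples: 0
seeds:
  simulate: 1
  dml: 1
  enrich: 1
  motif: 1
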