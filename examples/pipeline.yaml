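# Small end-to-end pipeline configuration: 6 subjects, traces for 3.
# Run:  riskcontext run --config examples/pipeline.yaml --out out/
task:
  n_trials: 240
  n_runs_range: [9, 10]
  length_range: [9, 36]
cohort:
  n_subjects: 6
  n_trace_subjects: 3
  miss_rate: 0.005
scr:
  cutoff_hz: 25.0
  n_coefficients: 16
  window_samples: 3
  floor: 0.02
  responder_fraction: 0.25
power:
  model: "2"
  term: prev_outcome
  n_sims: 25
  n_subjects: 10
seed: 0
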