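# Demo configuration: a small end-to-end run of the benefit-risk DCE
# pipeline on simulated respondents.  All randomness derives from `seed`.
mode: simulate
seed: 7
design:
  n_tasks: 36
  n_blocks: 3
  n_sweeps: 6
  repeat_position: 3
simulate:
  n_respondents: 120
  sigma: 0.8
  optout_rate: 0.05
estimation:
  n_draws: 100
metrics:
  kr_draws: 500
subgroups:
  - covariate: has_caregiver
    op: eq
    value: 1
    labels: [no_caregiver, caregiver]
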