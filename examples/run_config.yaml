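# Example pipeline configuration for `metacontrol run-all --config ...`.
# Omitted fields fall back to the study-design defaults (320-trial task,
# 50 agents per group, 100 restarts, 4 chains x 2000 iterations).
global_seed: 7
output_dir: metacontrol_run

task:
  n_blocks: 4
  trials_per_block: 80
  block_order: [stable, variable, stable, variable]

cohort:
  n_per_group: 10
  omega_effects:          # effect-coded coefficients on the mean omega
    age: 0.11
    stakes: 0.05
    transition: 0.04
    age_stakes: 0.12
    age_transition: 0.09

fitting:
  variant: standard
  n_restarts: 20

analysis:
  chains: 4
  iterations: 2000
  warmup: 1000
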