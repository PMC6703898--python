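"""Small parameter-recovery study: simulate agents at known parameters,
refit them, and correlate truth with estimates.

Truths are drawn from wide plausible ranges (Beta(2,2) for unit-interval
parameters, inverse temperature around 1.75 representing engaged agents).
At the study scale (50 agents, 20 restarts) the four condition-wise
model-based weights recover with correlations around 0.7-0.9; this demo
uses 15 agents to stay fast.
"""

import numpy as np

from metacontrol import TaskConfig, parameter_recovery
from metacontrol.fitting import recovery_truth_table

rng = np.random.default_rng(123)
truth = recovery_truth_table(15, rng)
report = parameter_recovery(truth, TaskConfig(), rng=rng, n_restarts=10)

print(f"agents: {report.n_agents}, "
      f"trials each: {report.config_summary['n_trials']}")
print(report.table.round(3).to_string(index=False))
print("\ncorrelation: truth vs estimate across agents; bias: mean estimate")
print("minus truth (prior shrinkage pulls beta down and omega toward 0.5);")
print("rmse shrinks roughly like 1/sqrt(trials).")
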