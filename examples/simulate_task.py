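"""Generate one session of the two-stage task and inspect its structure.

Builds the default 320-trial design (four alternating stable/variable
blocks, drifting planet rewards, reversals every 6-14 trials in variable
blocks) and prints its summary statistics.
"""

import numpy as np

from metacontrol import TaskConfig, generate_trial_sequence

config = TaskConfig(seed=1)
sequence = generate_trial_sequence(config)
frame = sequence.to_frame()

print(f"trials: {len(sequence)} in {config.n_blocks} blocks "
      f"({' / '.join(config.block_order)})")
print("stakes per block (should be 40/40):")
print(frame.groupby(["block", "stakes"]).size().unstack())

events = sequence.reversal_schedule.events
gaps = np.diff([t for t, _ in events])
print(f"\nreversals: {len(events)} (variable blocks only), "
      f"within-block gaps 6-14 trials")
print("reward walks: integer treasure in "
      f"[{frame.reward_red.min()}, {frame.reward_red.max()}] (red), "
      f"[{frame.reward_purple.min()}, {frame.reward_purple.max()}] (purple)")
print("\nEach row of the exported CSV is one trial: start state, stakes cue,")
print("both planets' current rewards, and whether a reversal took effect.")
print(frame.head(5).to_string(index=False))
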