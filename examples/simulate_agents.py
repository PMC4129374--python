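"""Simulate cohorts of model agents and compare their learning curves.

Generates a healthy-control and a heroin cohort from the VPP presets and
prints the mean net score ((#C + #D) - (#A + #B)) per 20-trial block.
Healthy-control agents learn toward the advantageous decks; heroin-preset
agents (near-zero loss aversion) do not.
"""

import numpy as np

import igtmodel as ig

schedule = ig.build_schedule()
for group in ("HC", "heroin"):
    preset = ig.get_preset("vpp", group)
    cohort = ig.generate_cohort(preset, schedule, T=100, seed=7)
    scores = np.stack([ig.block_net_scores(seq.choices)
                       for seq in cohort.dataset.sequences()])
    means = scores.mean(axis=0)
    print(f"{group:8s} (n={preset.size}) mean net score per block:",
          np.round(means, 1))
print("positive = mostly advantageous choices; rising = learning the task")
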