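"""Build the modified IGT payoff schedule and show its structure.

Decks A/B are disadvantageous (net -250 per 10-card block, escalating to
-1000), decks C/D advantageous (+250 to +375); A/C punish on 50% of
cards, B/D on 10%. Scaling by 100 maps the block-1 extremes to +1/-11.5,
the convention used by the cognitive models.
"""

import numpy as np

import igtmodel as ig

schedule = ig.build_schedule()
print("block net totals (rows = decks, cols = blocks 1..6):")
for deck in ig.DECKS:
    sums = [schedule.net(deck)[b * 10:(b + 1) * 10].sum() for b in range(6)]
    losses = (schedule.losses[deck][:10] < 0).sum()
    print(f"  {deck}: {[int(s) for s in sums]}   loss cards/block: {losses}")

scaled = ig.scale_net_outcomes(schedule)
block1 = np.concatenate([scaled.net(d)[:10] for d in ig.DECKS])
print(f"scaled block-1 extremes: max {block1.max():+.1f}, min {block1.min():+.1f}")
print("(the +1 / -11.5 calibration of the modeling scale)")
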