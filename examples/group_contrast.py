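"""Bayesian group contrast: loss aversion in controls vs heroin users.

Generates synthetic cohorts from the PVL-Delta presets of the two
groups, fits each separately, and prints the posterior of the
difference in the group-mean loss-aversion parameter. The 95% HDI
excluding zero (healthy controls above) reproduces the structure of the
published finding on synthetic data.
"""

import igtmodel as ig

schedule = ig.build_schedule()
cohorts = {}
for i, group in enumerate(("HC", "heroin")):
    preset = ig.get_preset("pvl-delta", group)
    cohorts[group] = ig.generate_cohort(preset, schedule, seed=i)

fits = {g: ig.fit_group("pvl-delta", c.dataset, ig.McmcConfig.desk(seed=i))[0]
        for i, (g, c) in enumerate(cohorts.items())}

for name in ("A", "alpha", "c", "lam"):
    con = ig.group_contrast(fits["HC"], fits["heroin"], name, seed=0)
    tag = "CREDIBLE" if con.credible else "not credible"
    print(f"{name:6s} HC - heroin: mean {con.mean:+.3f}, "
          f"95% HDI [{con.hdi.lower:+.3f}, {con.hdi.upper:+.3f}], "
          f"P(>0) {con.frac_positive:.3f}  -> {tag}")
print("a credible positive lam contrast = reduced loss aversion in the "
      "heroin-preset cohort")
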