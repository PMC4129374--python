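"""Parameter-recovery experiment: simulate, refit, compare to the truth.

Fifteen PVL-Delta subjects are drawn around the healthy-control preset,
their play is simulated, and the hierarchical fit's subject posterior
means are compared against the generating values.
"""

import igtmodel as ig

scaled = ig.scale_net_outcomes(ig.build_schedule())
preset = ig.get_preset("pvl-delta", "HC")
params = ig.sample_subject_parameters(preset, 15, seed=0)
summary = ig.parameter_recovery_experiment(
    "pvl-delta", params, scaled, ig.McmcConfig.desk(seed=0), seed=0,
    true_group_means=preset.means)

print(f"max R-hat {summary.max_rhat:.3f}")
print("per-parameter recovery (truth vs posterior mean across 15 subjects):")
for name in summary.correlations:
    print(f"  {name:6s} corr {summary.correlations[name]:+.2f}  "
          f"bias {summary.bias[name]:+.3f}  "
          f"95% HDI coverage {summary.hdi_coverage[name]:.2f}  "
          f"group mean in HDI: {summary.group_mean_in_hdi[name]}")
print("high corr + ~0.95 coverage = the parameter is well identified "
      "by 100 trials; learning rate and consistency recover best")
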