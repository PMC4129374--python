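# Methods

## The task and its payoff schedule

The Iowa Gambling Task (IGT) asks a player to draw cards from four decks
for up to 100 trials. In the modified schedule implemented here each deck
holds 60 cards in six blocks of ten. Decks A and B are disadvantageous:
each block nets −(250 + 150·(b−1)) task-currency units, reaching −1000 in
block 6. Decks C and D are advantageous: +(250 + 25·(b−1)), reaching
+375. A and C carry five loss cards per block (50% punishment
frequency), B and D one (10%).

The published description fixes block-level nets and loss frequencies
only. We complete the card-level schedule with the classic constant
per-card gains — 100 for A/B, 50 for C/D — and back-compute each block's
loss total from `net = gains − losses`, splitting it equally over the
block's loss cards. These gains are the unique classic values consistent
with the scaling calibration below (a block-1 deck-B loss card nets
100 − 1250 = −1150). Canonical loss positions within a block are fixed
({3,5,7,9,10} for five-loss decks, {9} otherwise); a seeded shuffle
variant permutes positions within blocks without touching block totals.
Draws beyond a deck's 60th card recycle the block-6 contingencies, since
a 100-trial session can exhaust a deck and the task description leaves
exhaustion behaviour open.

For modeling, all outcomes are divided by a fixed divisor, 100 by
default, chosen so the highest single-card block-1 net becomes +1 and
the largest block-1 net loss −11.5.

## Choice models

All models share three stages on the scaled net outcome x(t):

* Prospect utility: u = x^α for x ≥ 0, −λ·|x|^α for x < 0, with
  curvature α ∈ (0,2) and loss aversion λ ∈ (0,10). x = 0 takes the gain
  branch.
* A learning rule over per-deck expectancies E_j, with rate A ∈ (0,1):
  delta (only the chosen deck moves toward u) or decay-reinforcement
  (all decks decay by A, the chosen one gains u).
* Softmax choice with trial-independent sensitivity θ = 3^c − 1,
  c ∈ (0,5), so θ spans 0 (uniform) to 242 (near-deterministic). The
  softmax is computed with max-subtraction, exact at θ = 242.

PVL-Delta and PVL-DecayRI use the two learning rules with 4 free
parameters. VPP adds a perseverance strength P_j — decayed by k ∈ (0,1)
each trial, and incremented on the chosen deck by ε_p after gains or ε_n
after losses — and mixes V_j = ω·E_j + (1−ω)·P_j with RL weight
ω ∈ (0,1), for 8 parameters. Expectancies and perseverance strengths
start at zero, so trial 1 is uniform; trial t's probability uses the
state after outcome t−1.

## Hierarchical estimation

Each group is fitted separately. Subject parameters live on an
unconstrained raw scale: bounded parameters map through ξ = U·Φ(ξ′)
(Φ = standard normal CDF; U = 1, 2, 5, 10 for A/k/ω, α, c, λ), the
perseverance impacts ε_p, ε_n are unbounded. Raw values are exchangeable
normal, ξ′_i ~ N(μ, σ), with μ ~ N(0,1) (N(0,5) for unbounded
parameters) and σ ~ Uniform(0, 1.5).

Sampling is an adaptive Metropolis-within-Gibbs scheme compiled with
numba:

* single-site Gaussian random walks on each subject parameter, step
  sizes adapted toward 44% acceptance during warmup only;
* a per-subject joint proposal along the Cholesky factor of the
  subject's running posterior covariance (estimated during warmup,
  frozen afterwards), which handles the strong within-subject parameter
  correlations of the VPP model;
* conjugate normal draws for each group mean μ;
* a log-scale random walk on each σ, plus two interweaved non-centered
  moves — a translation (μ and all subjects' raw values shift together)
  and a rescaling (all subjects' standardised offsets are held fixed
  while σ moves) — which decouple the hypers from the subject block in
  the small-σ funnel regime.

The centered parameterization is used because the group means then admit
exact conjugate updates, which is what mixes well under conditional
sampling; the interweaved moves provide the benefits non-centering gives
gradient-based samplers. All adaptation stops at the end of warmup, so
retained draws come from a fixed-kernel chain. Chains are seeded
deterministically from the configuration seed.

The reference setting is 3 chains × (1000 warmup + 2000 retained); the
`desk` preset uses 3 × (500 + 500). Both retain every 4th post-warmup
sweep (`thin = 4`) — thinning buys mixing at fixed memory and keeps the
retained-draw counts at their nominal values. Convergence is summarised
per parameter by split R-hat and bulk ESS (arviz); any R-hat above 1.1
marks the fit non-converged in its report — flagged, never silently
dropped. PVL fits at desk scale typically reach max R-hat ≈ 1.05. The
8-parameter VPP model is weakly identified by 100 trials (ω, k and the
perseverance impacts have broad, correlated posteriors); its fits at
tractable lengths settle around max R-hat 1.15–1.3 on the worst
subject-level parameters while the loss-aversion hypers — the quantity
the group contrast uses — are stable across chains.

## Model comparison and simulation

WAIC is computed per subject from S = 1000 posterior draws subsampled
without replacement (seeded) from that subject's own posterior:
lppd = Σ_t log mean_s p(y_t|θ_s) (log-sum-exp), p_waic2 = Σ_t var_s
log p(y_t|θ_s) (ddof 1), WAIC = −2(lppd − p_waic2), summed over a
group's members. The p_WAIC1 variant is not provided.

Posterior-predictive simulation plays each subject's posterior-mean
parameters against the schedule n_reps = 100 times; per-trial deck
proportions are averaged within subject first, then across subjects,
and net scores are reported per 20-trial block.

## Synthetic cohorts

Nine presets (3 groups × 3 models) carry the published group-mean
estimates and their posterior SDs; group sizes are 48/38/43
(controls/amphetamine/heroin). The published SDs quantify uncertainty in
the group means, not between-subject spread, and the true
between-subject variance is unpublished, so cohort heterogeneity
defaults to 3× those SDs — a stand-in chosen once so that cohorts show
clear individual differences while group contrasts of the magnitude the
tables imply remain detectable. Native SDs are converted to the raw
scale by the delta method and subjects are drawn normally around the raw
image of the preset mean, which makes the preset mean the *median* of
the native generating distribution (monotone transforms preserve
quantiles, not means — the native mean shifts with skew, visibly so for
parameters near a bound such as A ≈ 0.01).

Synthetic cohorts emulate the trial-table format of the public IGT data
deposits (raw currency in files, scaling in memory) and ship a truth
sidecar of generating parameters. What passing tests on these cohorts
show is that the pipeline is self-consistent — data generated under the
assumed model family are recovered by it; they cannot show that real
participants follow these models, and the cohorts carry no demographic
structure, no outcome-history idiosyncrasies and no within-subject
nonstationarity.

## Problem sizes and numerical choices

The test suite exercises recovery at 15 subjects × 100 trials × 5 seeds
with the desk preset, and the loss-aversion group contrast on full-size
VPP cohorts (48 vs 43) at 3 × (600 + 500, thin 6) — sizes chosen to keep
the whole suite to a few minutes while leaving each check's verdict
stable across seeds. HDIs use the shortest sorted-window interval
(`ceil(mass·n)` samples); group contrasts pair draws from independently
fitted groups by seeded shuffle, down-sampling the longer set, since no
joint draw structure exists across fits. The contrast decision rule is
"95% HDI excludes zero"; an optional ROPE interval can replace the point
null. Degenerate inputs (empty sequences, single chains for R-hat,
non-positive divisors, S > available draws) are rejected with
messages naming the violated constraint.

## Known limitations

* The sampler trades gradient information for simplicity; VPP
  convergence at tractable lengths is approximate (see above), and very
  large cohorts would benefit from an HMC backend.
* Parameter recovery of α and λ is mediocre at 100 trials even for PVL
  models — a property of the design, mirrored in the original recovery
  analyses, not a defect of the fitter.
* The σ ~ Uniform(0, 1.5) prior is applied on the raw scale for all
  transform kinds, as specified for the reference analysis; for
  unbounded parameters this is informative relative to their N(0,5)
  mean prior.
* Real-data ingestion assumes the documented column layout; a
  column-mapping option adapts foreign headers but no further cleaning
  is attempted.
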