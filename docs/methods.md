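# Methods

## Task structure

A block enumerates every condition once: with n cues there are 2n
single-cue conditions (each cue on the left or the right), n² ordered
double-cue conditions (a pair of identical cues is one condition), and 2n²
perturbed double-cue conditions (each ordered pair with the rotation
applied to the left or the right cue) — 85 conditions for the standard
five-cue set (10 / 25 / 50).  Trial timing: 2000 ms fixation, 1000 ms cue,
1500 ms delay to reward; the perturbation starts 200 ms after cue onset and
lasts 100 ms.  All analysis times are milliseconds relative to cue onset;
the session clock is stored per trial.  In double-cue trials the rewarded
side is drawn with probability 0.5 independently of the perturbation, so
perturbations carry no reward information.

## Generative model

**Attention process.**  Attention is winner-take-all at every instant.
Single cue: that cue is attended throughout.  Double cue: the higher-value
cue is attended (ties broken uniformly).  A perturbation of the lower-value
cue captures attention with probability

    a = d / (1 + exp(c · |ΔV| / 8)),   clipped to [0, 1],

where |ΔV| is the value difference in drops and 8 the largest reward.  A
captured trial switches attention at perturbation onset + 100 ms (shift
latency, configurable) and stays switched; shifts are all-or-none per
trial, the time-averaged-weight reading of the model.  Within-trial
alternatives (graded mixing, intermittent switching) are not simulated;
nothing at these trial counts could distinguish them from the all-or-none
variant.  The generator's sigmoid argument is the *normalized value
difference*, while the fitting stage uses measured single-cue *response*
differences; keeping the latent drive and the fitted covariates separate
makes recovery tests honest (for a neuron with value gain g and visual
offset o the two differ by the factor κ = g/(o+g), absorbed by the fitted
c).

**Spike trains.**  Inhomogeneous Poisson with a rate that is piecewise
constant on a 10 ms grid spanning −2000…+1200 ms: baseline everywhere,
plus, from cue onset + visual latency (default 150 ms) until cue offset +
latency, a drive of the currently attended cue under a
transient-then-sustained envelope (50 ms linear ramp, 1.5× transient for
200 ms, then sustained), rectified at zero.  Sustained drive for attended
value V: `visual_offset + value_gain·V/8` (positive tuning),
`visual_offset + value_gain·(1−V/8)` (negative tuning), `visual_offset`
(untuned), 0 (non-visual).  The negative-tuning form gives those neurons
their largest response to the 0-drop cue, so the preferred-condition
normalization below is well-posed for both signs.  Defaults: baseline
5–15 spikes/s, value gain 12–28 spikes/s, visual offset 5 spikes/s —
ordinary prefrontal rates.  Because the rate is constant within grid bins,
per-bin Poisson counts are distributionally identical to binned spike
trains; the bulk simulator exploits this (`simulate_neuron_bin_counts`)
and a test checks the equivalence against the spike-train path.

**Pupil.**  500 Hz traces over fixation + cue + delay: a baseline, an
optional linear drift, Gaussian noise, and a value kernel that is zero
before cue onset, rises linearly over the cue period and holds through the
delay, with amplitude `amplitude_per_drop × attended value`.  The attended
value is the higher of the displayed values (perturbation effects on the
pupil are not modeled).  The post-cue-offset mean therefore exceeds
baseline by exactly amplitude × value in the noise-free limit, which the
pupil tests exploit.  Units are arbitrary tracker units; no millimeter
calibration is assumed.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated (non-Poisson) spiking, slow rate
drift, eye movements and microsaccades, blinks, reward-history effects,
session-to-session nonstationarity, and graded within-trial attention.

## Analysis pipeline

**Screening** (completed trials only).  Visually responsive: paired
two-tailed t-test of fixation-period vs cue-period rates (Student by
default; unpaired/Welch available), α = 0.05.  Value selective: one-way
ANOVA of 150–550 ms rates across the five values, single-cue trials pooled
over sides, α = 0.05.  Tuning: sign of the OLS slope of those rates on V.
Normalization: (condition mean − baseline) / (preferred single-cue mean −
baseline), baseline = 200 ms pre-cue mean, preferred cue = 8 drops
(positive) or 0 drops (negative); divisors below 0.1 spikes/s are
degenerate and the neuron is excluded with a log entry.

**Perturbation analyses.**  PSTHs use a 50 ms sliding window stepped by
10 ms (the window length is the defining choice; the step is ours),
baseline-subtracted and normalized to the peak preferred-condition
response.  The higher-rotated vs lower-rotated contrast is a two-tailed
t-test per bin on trial-wise windowed rates; BH-FDR at q = 0.05 corrects
the displayed population contrast.  A neuron is *modulated* if the
uncorrected pointwise p stays below 0.05 over a contiguous run of at least
200 ms inside 200–1000 ms (a run of k bins at 10 ms step counts as 10k ms;
ties resolve longest-then-earliest).  The contiguity rule is
anticonservative relative to a corrected test; its null behavior is
checked by simulation.  Z scores standardize each rotation group's mean by
the pooled trial-rate distribution of both groups in the modulation window
(or 200–1000 ms for unmodulated neurons; a uniform 450–750 ms window is
available).  MI = (FRh − FRl)/(FRh + FRl).  Consistency: a modulated
neuron is *consistent* if, averaged over value pairs, the
lower-cue-perturbed response sits closer to the perturbed cue's single-cue
response than the unperturbed double-cue response does.  The early-trials
control keeps the first 50 completed trials per block and subsamples
within each cue-combination stratum so perturbed and unperturbed counts
match.  Group contrasts that compare rotation conditions with the
no-perturbation condition restrict the unperturbed reference to unequal
pairs, because rotation targets only exist for unequal pairs — without
this composition matching the contrast is confounded by the equal-value
conditions.

**Model fitting.**  Condition means use the 200–1000 ms window on the
normalized scale, sides pooled into (higher value, lower value) pairs;
same-value perturbed pairs sit in the lower-perturbed bucket (their
prediction is Rh + b for any parameters).  Trials are split in half
stratified by condition; normalization factors come from all trials.  The
full model is fitted by bounded trust-region least squares
(b ∈ [−2, 2], c ∈ [0, 100], d ∈ [0, 2]) from 16 Latin-hypercube starts —
the objective is non-convex in c — and checked against a 50×50×50 grid
oracle in the tests.  Among numerically tied solutions the smallest-d one
is kept: when the data show no shift, (c, d) are free along a ridge and
parsimony favors the least-shift explanation.  Optionally,
higher-cue-perturbed and unperturbed double-cue means enter the objective
as offset anchors (their prediction is Rh + b regardless of c and d); the
default objective uses lower-cue-perturbed means only, higher-cue
perturbations being predicted with a = 0.  The constant-weight models
profile to convex quadratics in a and are solved in closed form (clamped
to [0, 1]); Model 1 shares a across the group with per-neuron offsets.
Evaluation is on the held-out half with test-half covariates:
cross-validated R² (1 − RSS/TSS about the test mean, may be negative) and
AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), with n the number of test
condition means (a trial-level convention is available) and k = 3 (full),
2 (Model 2), 1 + 1/G (Model 1: its own b plus an equal share of the group
weight; the attribution is configurable and reported).  Model 1's offset
is per neuron by default; a shared-offset variant is a flag.

**Pupil analysis.**  Baseline = mean 400–900 ms after fixation
acquisition (= fixation onset in the simulator); response = mean over the
1 s after cue offset minus baseline.  Single-cue responses regress on
drops (OLS, two-sided slope test).  The single- vs double-cue comparison
is a two-way ANOVA (reward size × cue count, double-cue trials grouped by
the higher value) with Tukey HSD post-hocs over value levels within each
cue-count stratum.  Session-level aggregation, where used, weights
sessions equally rather than by trial count.

## Validation studies and problem sizes

All studies live in `attnorm.studies`, are seeded, and are re-run both by
`tests/test_acceptance.py` and `scripts/acceptance.py`.

- **Combinatorics**: exact enumeration counts for the five-cue block.
- **Parameter recovery**: 200 neurons on the grid c ∈ {1, 2, 4, 8} ×
  d ∈ {0, 0.4, …, 2.0}, four blocks (340 trials) each — the scale of one
  recording session.  d spans its full range; c covers the regime where
  shifts are detectable at all, mirroring the fact that only significantly
  modulated neurons enter the fitted set (for larger c the weight is ≈0 at
  every observable value difference).  Zero-noise data are recovered
  essentially exactly (RSS < 1e−16).
- **Model selection**: 24 neurons per regime, 160 blocks each.  The
  per-neuron deviation of a sigmoid weight from the best constant weight
  is only ~0.05 normalized units, so condition-mean standard errors must
  be below that for the comparison to be about the models rather than the
  noise; that requires roughly an order of magnitude more trials than one
  session, which is the point of reporting it as a separate study.
- **Oracle equivalence**: optimizer vs dense grid search (20 instances),
  BH mask vs the hand-written step-up rule (1000 random p-vectors), AICc
  vs its closed form.
- **Pipeline signature**: 100 experiments of 12 positively tuned neurons
  at session scale; per experiment, paired t-tests across neurons of the
  higher- vs lower-rotated and higher-rotated vs no-perturbation group
  means, and a pooled regression of unperturbed double-cue responses on
  the higher and lower values jointly.  An equal-weight-averaging
  generator (drive = mean of the two values, perturbation inert) is the
  negative control: it makes the lower value a significant predictor.
- **Screening calibration**: 1000 zero-gain and 200 strongly tuned
  neurons, single-cue trials over nine blocks; the value-selectivity
  screen fires at ≈ the nominal 5% on the former and ≈ 100% on the
  latter.

## Known limitations

**Per-neuron d is weakly identified at session scale.**  d = 2·a(0) is an
extrapolation of the sigmoid to zero value difference, below the smallest
observable difference of 1/8 of the value range; c and d trade off along
the ridge d·exp(−c·|Rh−Rl|) ≈ const, and for data showing no shift the
likelihood is flat in d entirely.  With ~340 trials per neuron the
per-neuron error in fitted d has a standard deviation comparable to d's
own range (median |error| ≈ 0.4), so the rank correlation between true and
fitted d across neurons saturates near 0.3 at session scale and near 0.6
even at ten times that; grid-cell averages of the fits do track the truth
(reported as a calibration-curve diagnostic).  The offset anchors and the
parsimony tie-break above are mitigations, not cures.  Conclusions that
depend on d should be drawn at the population level, not per neuron.

Other limitations: the modulation-window contiguity rule is
anticonservative under the null (documented, simulated); equal-value
pairs carry no information about the attention weight (Rh = Rl); the
pupil model has no perturbation response, so pupillometric attention
capture cannot be studied here; and all calibrations inherit the
generator's Poisson assumption — overdispersed real data would need wider
bands.
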