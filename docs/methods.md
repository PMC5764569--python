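# Methods

This note documents the models, estimators and numerical choices behind
`striomix`, and what the synthetic-data validation does and does not
establish about real recordings.

## Synthetic experiment model

**Task schedule.** Cue identity (high/low reward probability) and reward
delivery are independent Bernoulli draws per trial (defaults 0.5 and 0.8/0.2).
Tones last 1.5 s; reward, when delivered, arrives 0.5 s after tone offset.
The inter-trial interval is defined as the gap from a trial's *outcome time*
(reward time, or tone offset + 0.5 s on unrewarded trials) to the next tone
onset, drawn uniformly from [5.25, 8.75] s; the anchor for "inter-trial
interval" is a modeling choice, since only its range is conventionally
reported.

**Licking.** Anticipatory licking is a piecewise-constant-rate Poisson process
during [tone onset, tone offset + 0.5 s]. A learning level in [0, 1] scales
the high/low cue rate separation around the common mean (defaults 6.0 and
1.5 Hz at full learning), and the rate is multiplied by
(1 + h_lick·1[previous trial rewarded]) with h_lick = 0.3 by default — mice
lick more in anticipation after a rewarded trial. Consummatory licking after
reward is a Poisson bout (7 Hz for 2.5 s by default) with **no** history
dependence; bout rate and duration are free parameters, not calibrated to real
mice, because only mean-rate curves are conventionally published. A 0.2 Hz
spontaneous rate runs throughout, and inter-lick intervals below 50 ms (a
physiological refractory floor) are pruned. Because anticipatory and
consummatory licking are generated independently, the pipeline's dissociation
— history-dependent anticipatory licking, history-invariant consummatory
licking — is a recoverable ground truth, not an artifact of the analysis.

**Neural tuning.** Each neuron has one preferred epoch (cue, post-reward
licking, post-licking, or none; population mix defaults to 6.5/21.8/4.2/67.5%,
i.e. ~38% task-responsive with the lick epoch dominating), a compartment label
(striosome with probability 0.269 by default; ~15% of striosomal and ~1% of
matrix neurons carry the red structural label directly), a peak-time offset
within its epoch, and event amplitudes drawn lognormally (fractions of
baseline fluorescence). The compartment gain profile applies a cue-gain
multiplier (default striosome 2.0 vs matrix 1.0, applied to cue-preferring
neurons) and a history gain h (default striosome 0.1 vs matrix 0.4) that
multiplies post-reward responses by (1 + h·1[previous trial unrewarded]).
An optional per-epoch amplitude scale models the empirical fact that cue
transients are weaker than post-reward consumption transients; the demo
configuration uses 0.45 for the cue epoch.

**Fluorescence.** Event amplitudes are impulses convolved with a
difference-of-exponentials indicator kernel (rise 0.2 s, decay 1.5 s —
literature-typical for GCaMP6s; configurable). Impulses are placed one
kernel-peak lag (0.47 s at the default kernel) before the intended peak time,
so a neuron's transient peaks at anchor + `peak_offset_s` — the quantity the
peak-recovery analyses measure. Spontaneous transients (0.18 Hz, exponential
amplitudes with mean 0.5) and Gaussian noise (σ = 65 fluorescence units on a
290-unit baseline) are calibrated so that baseline ΔF/F statistics land at a
realistic scale: mean ≈ 10%, SD ≈ 37%. A single shared neuropil signal (the
scaled population-mean transient signal) contaminates every somatic trace with
weight 0.7 and forms the ring traces, so the standard 0.7× annulus subtraction
removes it by construction.

**Movies.** Neurons are rendered as disjoint circular ROIs (striosomal cells
inside a dense structural-label zone, matrix cells outside). Both channels
carry static spatial speckle texture — dense neuropil labeling is spatially
structured, and that structure is what makes rigid registration well-posed in
both axes. Per-frame integer jitter is applied circularly and recorded; frame
0 is at rest. There is no point-spread-function or non-rigid motion model.

## Extraction

**Registration** maximizes normalized cross-correlation of each structural-
channel frame against a reference within ±10 px (integer shifts; circular
boundary, computed by FFT). The reference defaults to the pixel-wise mean of
all structural frames; because that mean is itself blurred by the motion, a
single pass recovers shifts only up to a constant offset. A second pass
against the sharp mean of the pass-1-registered frames, anchored to the first
frame, removes the offset; on synthetic movies this recovers every true shift
exactly up to the search radius. The same shifts are applied to the
functional channel, and registration computed from the functional channel
alone agrees frame-for-frame on the synthetic movies.

**Baseline F₀** is the mode of the trace's value distribution: the argmax of a
Gaussian KDE (Silverman bandwidth) on a 512-point grid spanning the data
range. The KDE is evaluated from a 4096-bin histogram rather than per sample
— with bins far narrower than the bandwidth this matches the direct
evaluation (asserted against `scipy.stats.gaussian_kde` in the tests) while
scaling to hour-long sessions. The estimator's bias is below 2% of true F₀
for transient occupancies up to 30%. The "mode of the fluorescence
distribution" reading of the baseline step is a design decision; the
originally described clustering procedure is not a standard named method, and
mode-of-density is its stated goal.

**Neuropil ring** geometry defaults to an annulus 2–6 px beyond the ROI
boundary, excluding all other ROIs; a ring left empty falls back to the
unsubtracted ROI mean with a warning. ΔF/F is reported in percent.
Resampling to the common 5 Hz analysis rate uses polyphase filtering with
mean-padding (fluorescence has a large DC offset; zero-padding would ring at
the session edges); upsampling is refused.

**Compartment labels**: striosomal ⇔ centroid inside the dense structural
neuropil zone OR the cell itself is labeled. The two sub-flags are stored
separately so labeled-outside-zone cells can be excluded in sensitivity
analyses.

## Epoch classification

Per trial and epoch, the response window mean is paired with the 1 s baseline
preceding **that epoch's own alignment event** (tone onset for the cue test;
first lick after reward for the licking test; last lick for the post-licking
test). Anchoring each baseline to its own event is essential with a
slow indicator: a cue transient decaying with τ = 1.5 s is still elevated
above the *pre-tone* baseline during the licking period, and a pre-tone-
anchored design therefore misclassifies cue neurons as lick-modulated. With
per-event baselines the decaying tail sits *below* its own pre-event baseline
and only genuine epoch-locked increases are flagged.

The default statistic is the one-sided Wilcoxon signed-rank test on per-trial
(response − baseline) differences — responses and baselines are paired within
trials — with the rank-sum variant selectable in the configuration. α = 0.01
is Bonferroni-corrected across the four tests (high-cue, low-cue, licking,
post-licking); the cue flag is raised when either cue condition is
significant, and epochs with fewer than 10 analyzable trials leave the neuron
indeterminate. Rank tests make the classification invariant to affine
rescaling of the raw fluorescence. Under the global null the empirical
task-modulated fraction stays within 1.5·α.

Trials in which the lick bout (maximal run of inter-lick gaps < 1 s; the gap
threshold is configurable, as "end of licking" has no conventional
definition) reaches the next tone onset are excluded — no end-of-licking time
can be assigned.

## Statistics

- **AUROC**: pair counting with ties at half weight; equivalently the
  Mann-Whitney U divided by n_a·n_b. Significance by a seeded two-sided
  permutation test (1000 label shuffles by default); the choice of a
  permutation test is a design decision. AUROC(a,b) + AUROC(b,a) = 1 exactly.
- **Reliability index**: mean Pearson correlation over all C(n,2) trial
  pairs; constant rows are skipped with a warning. Pearson (not Spearman) is
  used because the underlying quantity is the correlation of continuous
  traces.
- **Cross-neuron shuffle**: each trial's rows are permuted across the
  session's task-modulated neurons (a derangement, so no neuron keeps its own
  trial); 20 repeats are averaged per neuron and compared with the observed
  metrics by rank-sum tests. A permutation (rather than independent draws
  with replacement) is what preserves the population trial-mean field
  exactly, which is asserted to 1e-12; self-substitution is excluded because
  it would dilute the null. Sessions with fewer than 10 task-modulated
  neurons are skipped.
- **HMI**: per neuron, mean z over a 2 s window starting 1 s after reward
  delivery on currently rewarded trials, min-max scaled across that neuron's
  included trials (per neuron per session), split by previous-trial outcome
  regardless of the current cue, pooled over cue types. Zero range or a
  zero denominator excludes the neuron. The sign convention follows from the
  generator: h > 0 boosts responses after unrewarded trials, so HMI < 0.
  The cue-period history check uses the same machinery on the 2 s post-tone
  window without min-max normalization (z-scores are the conventional scale
  there).
- **Learning criterion**: per-session two-sided Welch t-test (the
  unequal-variance form is a design decision) on anticipatory lick counts
  during the tone plus the 0.5 s delay (the delay's inclusion is
  configurable). The trained flag is raised at the first session s whose
  trailing window of up to three sessions contains at least two significant
  ones; that session is the first criterion session. The rule's true null
  firing probability across 20 sessions is ≈ 8–9% at α = 0.05.
- **Region-pair ANOVA**: paired striosome/matrix region traces are z-scored
  to the last 1 s of the inter-trial interval (the second before each tone
  onset), averaged over the tone window per session × compartment × cue, and
  analyzed with a repeated-measures ANOVA (subject = session) plus paired
  post hoc t-tests.
- **Session regression**: ordinary least squares with intercept (per
  compartment and pooled); the combined model uses licking as the sole
  regressor so its residuals carry the compartment contrast, compared by a
  paired t-test across sessions. With equal session counts the two
  compartments' mean residuals are exact negatives (residuals of an
  intercept model sum to zero), asserted to 1e-10.

## Problem sizes

The demo configuration runs one synthetic mouse: 20 training sessions of 60
trials (behavior + paired neuropil regions) and one post-criterion imaging
session of 240 neurons × 240 trials, plus a 40-frame two-channel movie for
the registration demonstration; it completes in well under a minute on one
CPU. The parameter-recovery suites use 200 neurons × 300 trials (cue
contrast, 20 seeds) and 200 neurons × 250 trials (history contrast, 20
seeds). These sizes were chosen so each contrast has clear statistical power
at a scale a single imaging session could plausibly provide.

## What passing tests show — and what they do not

The synthetic generator shares the analyses' structural assumptions: linear
amplitude-to-fluorescence mapping, a single shared neuropil source matched to
the 0.7 subtraction factor, Poisson licking, integer rigid motion, Gaussian
noise. Passing recovery tests therefore demonstrates that the pipeline's
estimators are correct and well-calibrated under the stated model — not that
the model captures real tissue. In particular: real neuropil contamination is
spatially heterogeneous and not exactly 0.7×; real motion has sub-pixel and
non-rigid components; real indicators are nonlinear at high rates; and real
compartment contrasts are entangled with behavioral variability in ways the
generator only schematically reproduces (a single learning-level scalar).
The generator also contains no reward-omission or prediction-error machinery
beyond the one- and two-back outcome labels.

## Known limitations

- No spike inference or deconvolution; all analyses operate on ΔF/F.
- No automated ROI segmentation; masks are inputs.
- No bleaching correction and no sub-pixel registration.
- Repeated-measures ANOVA requires complete session × compartment × cue
  cells; incomplete sessions are dropped.
- The HMI pools cue types; cue-conditioned history indices are not computed.
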