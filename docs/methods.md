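# Methods

## Generative design

The stimulation process has two hidden binary sources
`u(t) = (u1(t), u2(t))`, i.i.d. Bernoulli(ρ) per one-second event, and 32
binary channels: at each event every channel in the first half copies `u1`
with probability *a* (otherwise `u2`), and every channel in the second half
copies `u2` with probability *a*.  Equivalently the channel intensities are
`A u(t)` with mixing rows `(a, 1−a)` / `(1−a, a)`.  Defaults are ρ = 1/2,
a = 3/4, 256 events per trial, 100 trials, 32 stimulation channels among 64
electrodes.  One schedule realization (both `u` and `s`) is drawn per culture
and replayed on every trial; this matters for the statistics, because the
realized conditional frequencies of a 256-event pattern differ from their
expectations, and every downstream estimate is conditional on the realized
pattern.

Two consequences worth keeping in mind:

* A unit that simply follows one first-half channel has an *expected*
  pure-state response ratio `x̄^{(1,0)}/x̄^{(0,1)} = a/(1−a) = 3`, but its
  realized ratio on one schedule fluctuates with the ~64 events per state.
  Monte-Carlo estimates of the expectation therefore pool channel-follower
  units across several schedule realizations.
* Analyses that compare cultures treat each culture as having its own
  schedule realization; a schedule shared across cultures leaves a
  common-mode bias that does not average out.

## Culture simulator

Per event, the latent 2-D population rate is `x̃ = W s̃ + ξ` where `s̃` is
the channel-group mean input and `ξ ~ N(0, Σ_ξ)`.  Each stimulated electrode
`i ≤ 32` has expected count `baseline + local_gain · s_i + x̃_g(i)` (its own
channel plus its group's population rate); non-stimulated electrodes couple
weakly (`bg_gain`) to the mean population rate.  Rates are rectified at zero
and emitted as Poisson counts.  After each trial the connectivity updates by
the state-dependent Hebbian rule
`W ← W + η Σ_u β_u z^u`, with `z^u` the within-trial centered cross-products
of the *observed* count group means with `s̃` — plasticity is driven by the
activity the culture actually produces, not by a noiseless latent signal.
The silent state `(0,0)` has efficacy 0 (no activity, no activity-dependent
plasticity).

**Reliability gain.**  While plasticity is active, the background-noise
standard deviation decays by `noise_decay` per trial.  This models the
consolidation of evoked responses with training: trial-to-trial response
variability falls as the network adapts.  Without it, a purely linear-Poisson
observation model cannot lower the prediction-error term of the free energy —
the residual covariance is background noise plus Poisson group-mean variance,
and the Poisson part *grows* with the response rates.  Blocking plasticity
(`apv_mode`) freezes the noise level too, which is what makes the blocked
condition flat in all energy terms.

### Default parameters

| parameter | default | units | role |
|---|---|---|---|
| `W0` | [[2.8, 0.8], [0.8, 2.8]] | spike/event | initial connectivity, weakly selective |
| `beta1`, `beta2` | 0.01, 0.00271 | gain | efficacies; ratio 27.1 % |
| `eta` | 0.05 | – | plasticity step scale |
| `noise_cov` | 2.25·I | (spike/event)² | background noise at trial 1 (sd 1.5) |
| `noise_decay` | 0.9975 | /trial | reliability gain while plastic |
| `baseline` | 0.5 | spike/event | spontaneous rate |
| `local_gain` | 2.0 | spike/event | direct response to own channel |
| `bg_gain` | 0.15 | – | non-stimulated-electrode coupling |

These values place the simulator in the regime the analysis is designed for,
and were fixed once from replicated pilot runs before the test suite was
frozen: population clusters for the four source states *overlap* at trial 1
and separate over training (so the mixture entropy can rise while the
residual shrinks); within-group connectivity grows while between-group
connectivity declines; all 32 stimulated electrodes clear the availability
threshold while the non-stimulated ones do not; and the response scale is
large enough that the learning-rule estimator's known small-sample bias
(below) stays within Monte-Carlo tolerance of the true efficacy ratio.  The
spontaneous-activity level and per-electrode gain of real cultures are not
constrained by the design, so `baseline`, `local_gain` and `bg_gain` are free
parameters of the emulation, not calibrated claims about tissue.

### What the simulator does and does not emulate

Emulated: the mixing design and its four-state structure; per-electrode
direct vs population-driven responses; Poisson count statistics;
state-dependent Hebbian drift of the population connectivity; training-linked
reliability gain; plasticity blockade; partial-training schedules (plasticity
active only in the first and last ten trials).  Not emulated: biophysical
neuron or electrode models, spontaneous bursting, spike waveform diversity,
electrode crosstalk, non-stationary excitability, or any homeostatic
constraint on total synaptic strength.  The last omission is visible: with
the state-dependent rule and efficacy ratio 0.271, the per-trial diagonal
growth `A + B` and off-diagonal change `−(A − B)` (with
`A = 8ηβ₁(w₁−w₂)`, `B = 16ηβ₂(w₁+w₂)`) satisfy `B/A ≥ 0.54` for any positive
cross-coupling, so diagonal growth always outpaces off-diagonal decline by at
least ~3×, and no norm of `W` is conserved during training.  Real cultures
show a more norm-conserving trajectory, suggesting normalization mechanisms
outside this rule.  Consequently, passing tests demonstrate the estimators
and the direction of the documented effects under the stated generative
model — not that real tissue obeys that model.

## Preprocessing

Traces are 25 kHz.  Artifact handling zeroes saturated samples, applies a
zero-phase 4th-order Butterworth band-pass at 500–2000 Hz
(`scipy.signal.sosfiltfilt`; the design order is a package choice — only the
band is fixed by the recording convention), and re-zeroes the flagged
regions.  Spike detection computes mean and SD per non-overlapping 1-s block
(shorter traces use their full span), takes local minima
(`v[k] < v[k−1]` and `v[k] ≤ v[k+1]`, ties broken leftward) below −5 SD, and
keeps only the deepest valley within any 0.25 ms.  Evoked counts use the
half-open latency window [10, 30) ms — half-open so a boundary spike is never
counted twice — and refuse inter-stimulus intervals shorter than the window.
Count-based pipelines (including everything the simulator feeds) bypass this
module entirely.

## Response statistics

Conditional means `x_i^u` are per-trial averages over the events of each
source state; a state absent from a trial yields a missing cell that is
excluded (not zero-filled) from all-trial averages.  Availability and
preference use the thresholds above.  The Poisson KLD uses limit conventions
`λ₁ = 0 → D = λ₂`, and for `λ₂ = 0` the divergence is +∞ unless a floor is
supplied; the per-trial transition curves floor `λ₂` at one pseudo-count over
the run (`1/(n_trials · n_events)`), which keeps curves finite without
reordering them.  Change-from-trial-1 summaries clip deltas to ±10 nats.
Coding diagnostics correlate each electrode's event series, concatenated over
all trials, with the sources and with the population error signals
`e_k(t) = x̃_k(t) − (Σ x̃_k / Σ u_k) u_k(t)`; zero-variance series yield NaN
and flag the electrode.  Thresholds (0.4 correlation, 0.5 preference,
1 availability, ±10 clip, 3× source-coding ratio) are exposed as arguments
with these defaults.

## Population model and free energy

The population series uses available, preferring electrodes only; a culture
without both groups is excluded with a diagnostic.  Connectivity is estimated
per trial by the closed form above (singular or ill-conditioned input moment
matrices — condition number > 1e8 — raise, naming the trial).  The residual
covariance is pooled over the trial's events; a state-conditional variant is
available (`conditional_residual_covs`) but the pooled form is the default
because the expected-energy closed form involves a single noise covariance.
Recognition-density components are conditional sample moments (no EM — the
states are known); trials with fewer than two events in a state are flagged
missing.  Covariances are ridge-regularized by `1e-9 · trace/2` on the
diagonal before inversion or log-determinants, which handles degenerate
trials with constant responses.  The entropy is the plug-in average of
`−log q` at the trial's observed points, computed with `logsumexp`.
`F = ⟨U⟩ − H` holds as an exact identity on every output row; the entropy of
the connectivity posterior is omitted as trial-constant under a fixed
schedule.

## Learning-rule estimation

Hebbian statistics are centered with within-trial means (the defining sums
run within one trial); all-trial centering is available behind a flag.  The
response variable is the constant average change
`dW = (W(last) − W(first)) / n_trials` — the per-trial differences are noisy
and the trajectory saturates late, so the average is the stable summary.
Both estimators are Gaussian maximum-likelihood closed forms with one shared
residual variance across the four matrix entries; the ML variance is floored
at a scale-relative epsilon (1e-20 of the mean-square response) so that two
exact fits compare as equally good rather than by rounding noise.  BIC is the
Schwarz criterion `k ln n + 2·NLL` with `n = 4 · n_trials` residuals and
`k = 2` (α-model: efficacy + variance) or `k = 3` (β-model); either
convention for counting the variance preserves the one-parameter penalty
difference that the model comparison rests on.

**Known bias.**  Holding `dW` constant while the regressors `z^u(l)` trend
upward with the growing connectivity attenuates the coefficients unevenly;
under the default conditions this inflates the recovered efficacy ratio by
roughly one to two percentage points (a per-trial regression against the
exact trajectory recovers the ratio exactly).  The default response scale
was chosen so this bias stays small relative to the between-culture
Monte-Carlo spread; it shrinks further as the relative connectivity growth
over a run decreases.

## Statistical tests and pipeline

Group summaries use the Wilcoxon signed-rank test for paired comparisons,
Mann-Whitney U for unpaired, and Spearman rank correlation, via
`scipy.stats`; every reported p-value carries its test name and n, and
all-tied paired data is reported as degenerate rather than tested.  The
pipeline is deterministic under a fixed seed (named RNG substreams per
component, independent per-culture seeds), records a configuration hash
excluding output location, and logs excluded electrodes and cultures per
stage.  Reported experiment sizes follow the study design: 23 cultures for
the training condition, 9 for plasticity blockade, 100 trials x 256 events;
the bundled statistical checks run these sizes directly.

## Limitations

* The linear-rate, Poisson-count observation model is the analysis model;
  model mismatch on real recordings (bursting, saturation, electrode drift)
  is not represented.
* The reliability-gain mechanism is phenomenological; the package makes no
  claim about its biological substrate, only that blocked-plasticity
  cultures do not show it.
* The γ-norm of the connectivity is computed and reported, but no stability
  pattern across γ is asserted for simulated cultures (see the simulator
  section for why the generative rule cannot produce one).
* Learning-efficacy recovery is validated for the regime around the default
  parameters; far outside it (very small steps, very low rates) the
  endpoint-noise and trend biases of the constant-`dW` regression grow.
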