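# Methods

## The trigger model

The model decides, at every millisecond of a tracking trial, whether to keep
pursuing smoothly or to commit a catch-up saccade.

**State estimation.** The observer tracks the pair (PE, RS) — position error
in degrees and retinal slip in deg/s — with a Kalman filter. Internal
dynamics: PE integrates RS exactly (d PE/dt = RS) plus a random-walk term
(`pos_process_sd`, default 3 deg/√s) standing in for unmodeled target jumps;
RS is a random walk with diffusion `process_sd` (default 30 deg·s⁻¹/√s).
Without the PE random-walk term the filter's position gain collapses once it
has converged and a target step goes almost unseen for hundreds of
milliseconds; with it, steps are absorbed within a few tens of milliseconds,
which is what fixation/step behavior looks like. Observations of both
components arrive with a fixed afferent delay (`sensory_delay`, 50 ms) and
independent Gaussian noise:

- position sd = `pos_sd_clear` (0.5°) or `pos_sd_blur` (2.5°, the blurred
  target), multiplied by (1 + `pos_sdn_coef`·|RS|) with `pos_sdn_coef` = 0.1
  per deg/s — motion smear: a fast-slipping target is harder to localize,
  and blur degrades the smeared image proportionally;
- velocity sd = `vel_sd_base` (1 deg/s) + `sdn_coef`·|RS| (0.2) —
  signal-dependent noise in the motion channel.

During a saccade, vision is suppressed: no measurement updates while in
flight, none for delayed samples recorded mid-flight, and delayed position
samples are corrected by the saccadic displacement executed since their
source time (corollary discharge). At saccade offset the estimate is shifted
by the executed amplitude. Without this bookkeeping the observer re-reads
its own stale pre-saccadic error and perseverates, re-triggering the same
saccade.

**Decision.** The PE belief is extrapolated `dt` = 150 ms ahead
(PE_pred = PE + dt·RS; variance propagated through the same linear map).
Confidence is the log probability ratio of the extrafoveal mass on the
dominant side against the foveal mass of the Gaussian belief
(`foveal_radius` 1.5°), computed in log space so confident beliefs do not
underflow. Positive confidence accumulates at its instantaneous rate,
saturated at `rate_cap` (35 s⁻¹; confidence discrimination saturates — a 10°
and a 20° predicted error are equally obviously extrafoveal), with negative
increments floored at zero and an optional leak (default off). The
accumulator resets at each target step and after each executed saccade, so
the first post-step saccade is the response to that perturbation. The
threshold (0.75) carries lognormal trial-to-trial variability
(`threshold_cv` 0.2), the LATER-style account of latency dispersion.

**Motor output.** Crossing the threshold commits a saccade after a 100-ms
motor delay, aimed at the predicted error at the expected landing time
(motor delay plus half the saccade duration) with mild endpoint noise
(5% of amplitude + 0.1°). Kinematics are a symmetric minimum-jerk
displacement with main-sequence duration 2.2 ms/deg·|A| + 21 ms. Pursuit
runs in parallel: eye acceleration relaxes the velocity toward
`pursuit_gain` (0.9) times the estimated target velocity with a 100-ms time
constant plus a small velocity diffusion (1 deg·s⁻¹/√s).

**Timing anatomy.** A trigger time decomposes into the 50-ms afferent
delay, ~10-30 ms of estimate convergence, the accumulation time
(threshold/rate, ≥ ~21 ms at the cap) and the 100-ms motor delay. The
earliest saccades therefore land just under the 175-ms early/late boundary,
and the early/late bimodality emerges from the accumulation term alone. The
threshold, cap, foveal radius and noise magnitudes were set so that the
clear-condition median trigger time at large |PE_pred| sits in the
150–200 ms range and the qualitative contrasts below hold; all are plain
config fields, not hidden constants.

## Task generator

Trials follow the double step-ramp design: fixation at ±20°, a first
position step of 2/4/6° away from the screen center with a ramp of
10/20/30 deg/s back toward it, a 500–700-ms steady period, then the probe:
a velocity step VS ~ U(−50, 50) deg/s **added to the running ramp** and a
position step PS drawn given VS from [−20, 20]° ∩ {|PS/VS| ≤ 1 s}
(continuously by default; a 2°-grid discrete mode is available). Treating
VS as a velocity change (not an absolute velocity) is what makes
T_xt = −PS/VS exactly the time at which the stepped target re-crosses its
original trajectory, which a property test verifies against the generated
trajectories. Trajectories end at the screen edge (±30°) when a fast ramp
reaches it, provided at least 800 ms after the step remain — enough for the
400-ms classification window plus any late saccade; step combinations that
cannot stay on screen that long are resampled, mirroring the omission of
off-screen steps from the design. Sessions alternate clear and blurred
targets, 10 sessions × 10 blocks × 50 trials per participant (5000 trials;
15 participants = 75,000) in the full design; the scaled study used
throughout the analyses is 10 participants × 2 sessions × 2 blocks × 50
trials = 2000 trials, which keeps every directional contrast estimable in
about a minute on one core.

## Synthetic data

`model` mode runs the closed-loop model above. `scripted` mode synthesizes
pursuit as a first-order lag (gain 0.9, 100-ms latency, 80-ms time constant)
on the delayed target velocity and places saccades by a fixed deterministic
rule with known onsets and amplitudes — plumbing for validating the detector
and metrics against exact ground truth, not a scientific claim. Blinks are
100–300-ms NaN gaps near the second step; dropouts are isolated NaN samples.
What the generator does **not** emulate: anticipatory pursuit, pursuit gain
adaptation across sessions, binocular disparity, microsaccades, pupil
dynamics, or tracker-specific artifacts — so green tests certify the
pipeline's correctness and the model's qualitative behavior, not fidelity to
any individual human record.

## Analysis chain

Eye position is low-pass filtered (2nd-order Butterworth, 50 Hz cutoff,
forward-backward for zero phase; NaN gaps are bridged for filtering and
restored after), differentiated by central differences (exact for ramps;
applied twice for acceleration). Saccades are spans where |acceleration|
exceeds 750 deg/s², merged across gaps under 20 ms, discarded under 10 ms
(filter-ringing artifacts), with edges refined to the 5%-of-peak velocity
crossings between the flanking velocity minima: the zero-phase filter smears
the transient symmetrically, so fractional-height crossings recover the true
onset within ~2 ms where the raw velocity minimum lands ~6 ms early. Event
direction is the sign of the velocity excursion from the local pursuit
baseline (net displacement misleads for small saccades riding fast opposite
pursuit).

Target velocity is taken from the trial's commanded segments rather than by
differentiating the target channel (a position step would otherwise inject a
spurious velocity impulse). Exclusions: NaN gaps during or after the second
step; a saccade in flight at the step; double saccades (post-step
inter-saccadic interval < 100 ms, applied to pairs starting inside the
400-ms window that contains the analyzed first saccade); and a first
saccade directed against the outstanding position error when |PE| > 0.5°
(a saccade to the first ramp's trajectory). T_xe = −PE/RS returns an
undefined marker when |RS| ≈ 0 and such trials drop out of T_xe binning
only. Pre-saccadic sampling takes instantaneous PE/RS 100 ms before the
first post-step saccade (clipped to the step and flagged if the lead reaches
back past it); smooth trials — no saccade onset within 400 ms — use the
400-ms post-step average instead. PE_pred at the step averages over
[step, step+50 ms). Classes: early < 175 ms ≤ late < 400 ms ≤ smooth.

## Group statistics

Bins are half-open [lo, hi): PE_pred coarse {(−∞,−5), [−5,5), [5,∞)} and
fine 2° bins over [−20,20); T_xt {(−∞,0), [0,400), [400,∞)}; T_xe 50-ms
bins over [−400,600); |VS| in five 10-deg/s bands. Per subject × condition
× bin, trigger-time medians and IQRs use linear-interpolation quartiles
(stated because IQRs depend on the convention) over saccade trials only,
with a minimum of 5 saccade trials per cell (cells below report missing,
not zero). Repeated-measures ANOVAs (pingouin) drop incomplete subjects
listwise and report partial η²; post-hocs are paired t tests with Bonferroni
multiplication capped at 1; Bayes factors use the BIC approximation
BF₁₀ = exp((BIC_null − BIC_alt)/2) on subject-plus-factor linear models —
an order-of-magnitude instrument, not a replication of any package's exact
numbers.

The extrapolation-horizon recovery uses the smooth-zone identity
(PE_pred = 0 exactly when T_xe = dt): smooth trials hold PE ≈ −dt·RS, so
scanning candidate horizons for the one minimizing Var(PE + dt·RS) across
smooth trials recovers the generating dt. Scanning instead for the horizon
minimizing within-PE_pred-bin trigger-time variance does not work here:
trigger times carry the accumulation history from the step, not just the
decision-time error, and that scan drifts high.

The velocity-step contrasts condition on matched errors, because the design
couples step size to velocity (|PS| ≤ |VS|·1 s): smooth-zone narrowing is
the saccade proportion for T_xt ∈ [40, 180) ms rising from the lowest to
the highest |VS| band, and the signal-dependent-noise effect is the median
trigger time of the high-|VS| half exceeding the low half in a majority of
matched 2° PE_pred bins. Unconditioned |VS| comparisons are dominated by
the coupling (low-|VS| trials necessarily carry small predicted errors) and
are not meaningful tests of the noise mechanism.

## Numerical and design notes

- All randomness flows from a single `numpy` Generator per run; datasets,
  simulations and metrics are bit-reproducible under a fixed seed.
- Normal tail probabilities use erfc with an asymptotic Mills-ratio branch
  beyond 7 sd, keeping log ratios finite out to arbitrarily confident
  beliefs; a zero-variance belief returns ±∞ log ratio (point mass).
- The Kalman step is scalar 2×2 arithmetic with symmetrization of the
  cross term; the covariance is validated positive semidefinite at the API
  boundary.
- The 120-Hz display refresh of the original apparatus is not modeled;
  trajectories live on the 1000-Hz analysis grid.
- Prior covariance at trial start is diag(1, 25) (broad); its value is
  unverified against the antecedent modeling work and only matters for the
  first ~100 ms of fixation.
- Known limitations: horizontal (1-D) tracking only; no acceleration
  sensory channel; no likelihood-based fitting to human data; the scripted
  trigger rule is intentionally unphysiological.
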