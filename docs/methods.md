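# Methods

`myoexo` models a single-session treadmill study of a portable ankle
exoskeleton under proportional myoelectric control, and the analysis used
to quantify neuromechanical adaptation to it. Because no raw recordings
of such a session are publicly deposited, the package pairs the analysis
pipeline with a synthetic gait/EMG generator whose parameters encode the
study regime; every analysis stage is then testable against known ground
truth. This note documents the models, the defaults and why they were
chosen, and what the synthetic data do and do not establish.

## The controller

The control signal is the linear envelope of the soleus surface EMG:

1. causal 2nd-order Butterworth high-pass, 50 Hz cutoff;
2. full-wave rectification;
3. causal 2nd-order Butterworth low-pass, 8 Hz cutoff.

All controller filters are forward-only with zero initial state: the
device runs in real time, so sample *t* of the command can depend only on
inputs up to *t* (the test suite asserts this prefix-invariance).
Offline analysis elsewhere in the package may use zero-phase filtering;
the controller never does. The first 2 s of any calibration statistic are
discarded to drop the filter start-up transient.

A subject-specific static gain maps envelope to motor q-axis current,
determined during unpowered walking so the command reaches the 7.6 A
current cap (the vendor-stated line-to-line equivalent, 20 A, is stored
as an informational constant and never computed with). Two calibration
conventions are implemented, because how the deployed gain anchored the
envelope to the cap is underdetermined:

- **absolute max** — gain = 7.6 / max(envelope over the window). This is
  the formula used when no stride segmentation is available.
- **stride-mean max** (pipeline default when stride events are known) —
  gain anchors the peak of the 30-stride *mean* envelope curve to 7.6 A.
  Individual strides above the mean then saturate at the cap, so the
  command still reaches 7.6 A on the calibration bout, but the session
  gain is no longer set by the single largest stochastic excursion of the
  envelope estimator. The absolute-max convention makes the gain an
  extreme-value statistic whose bias grows with bout length and
  systematically understates typical per-stride currents; the mean-curve
  convention is an asymptotically unbiased estimate of the model gain,
  which is also what makes noise-free reference values recoverable.

A deadband zeroes the command wherever the envelope is below 5% of the
calibration maximum, making the device transparent during swing; current
is clipped to [0, 7.6 A]; torque is current times a transmission ratio
and is plantarflexion-only. The default transmission is a constant
2.2 Nm/A — peak torque 16.7 A·Nm/A ≈ at the cap, inside the 7–17 Nm range
such devices produce on day one — with a tabulated ratio-versus-angle
hook (linearly interpolated, clamped at the table hull) for hardware with
a genuinely variable transmission.

## The synthetic session

The default timeline is Boots Only 5 min, Unpowered 5 min, Powered
30 min, Deadaptation 10 min — 50 minutes of walking per subject, 12
subjects. Stride period is 1/0.9 s with 3% stride-to-stride and 5%
between-subject variation (typical treadmill values; the source protocol
does not report cadence). Body mass 69.3 kg and walking speed 1.15 m/s
are the study's group means; all synthetic subjects share the mass, since
the analysis normalizes to body mass anyway.

**EMG.** Each muscle's envelope is a sum of Gaussian bursts in %-cycle
(circularly wrapped so bursts near heel contact stay continuous): soleus
has an early-stance shoulder plus a push-off burst peaking at 47% so that
plantar-flexor drive spans stance; the gastrocnemii peak slightly
earlier; tibialis anterior is active in swing and around heel contact.
Raw EMG is the envelope modulating unit-RMS Gaussian noise band-limited
to 20–450 Hz, plus a 0.01 mV noise floor — the standard amplitude-
modulated-noise surrogate that preserves envelope statistics without
modeling motor-unit physiology. Per-stride envelope amplitude jitters
log-normally with CV 8%; subjects carry a log-normal overall gain
(σ = 0.2) that cancels under the Boots-Only normalization.

**Adaptation.** Practice with the powered device scales each muscle's
envelope by 1 + Δ·(1 − e^(−t/τ)) with t the powered walking time. The
steady-state changes Δ are the study's end-of-practice group effects:
soleus −12%, medial gastrocnemius −5%, lateral gastrocnemius −17%,
tibialis anterior +9%. τ defaults to 5 min, so the 30-minute bout reaches
>99% of steady state; only end-of-practice changes are reported by the
study, and a single-time-constant approach is the simplest dynamics
consistent with an "adaptation period". After power-off the factor decays
back toward 1 with the same τ, giving a D1 after-effect and a mostly
washed-out D2. Between-subject spread of Δ is Gaussian with SD 0.03 —
deliberately small so that 12 subjects identify the group effect to
within the ±3-percentage-point recovery tolerance; real between-subject
heterogeneity in such studies is several times larger (individual percent
changes from −37% to +35%), which is exactly why the human result was
statistically null. Passing recovery tests here validates the pipeline's
estimators, not the detectability of the effect in humans; the generator
can emulate the human-scale heterogeneity by raising
`subject_adaptation_sd`, at which point group ANOVAs become
non-significant as in the study.

**Mechanics.** Sagittal ankle/knee/hip angles and moments are monotone
cubic (PCHIP) templates in %-cycle, evaluated per stride; vertical GRF is
a double-bump stance profile, exactly zero in swing, with sharp onset and
offset ramps plus loading/pre-swing shoulders so threshold crossings land
within one 100 Hz sample of the true stance boundaries (the generator's
ground-truth events are recoverable by the detector to ±1 sample). The
ankle angle and moment knots were calibrated once, against the noise-free
reference computation below, so that the device contribution sits in the
published regime — exoskeleton ≈ 0.63 W/kg peak power, ≈ 28% of peak
total power, ≈ 17% of peak total moment, ≈ 35% of positive work — and
then frozen.

**Device angle.** The exoskeleton's reported ankle angle is an affine
compression of the biological angle (scale 0.44, offset 4.8°),
reproducing the observed range-of-motion deficit (biological 5° DF–20° PF
against device 7° DF–4° PF in unpowered walking): shank-cuff stretch and
soft-tissue motion decouple the device encoder from the joint. A
consequence of the affine model is that device-frame angular velocity is
0.44× biological everywhere, which is a stronger compression at push-off
than devices actually show; for that reason the ankle decomposition
computes exoskeleton power in the biological-angle frame by default
(making total = biological + exoskeleton power exact) and exposes the
device-frame power both as a reported curve and via `use_exo_angle=True`.

## The analysis

Strides are segmented by threshold crossing of vertical GRF (20 N,
debounced at 0.4 s); each stride is linearly resampled onto a 101-point
0–100% cycle grid with heel contact at 0%, and the per-stride toe-off
fraction — not a fixed 60% — splits stance from swing. Analysis windows
are the last 30 strides of Boots Only, Unpowered, Powered (PoweredEnd)
and Deadaptation (D2), and the first 30 of Powered (PoweredStart) and
Deadaptation (D1).

EMG cycle curves are normalized per subject and muscle to the maximum of
the Boots-Only *mean* curve (robust to single-stride spikes). The scalar
outcome is stance-phase RMS (swing for tibialis anterior), computed per
stride and averaged (pooling is available). Percent change is
100·(b−a)/a; the standardized mean difference is |mean difference| over
the mean of the two SDs, with 0.3 the conventional "small" threshold.
(The study's printed SMDs numerically equal percent-change/100, which is
inconsistent with its own stated SD-based formula given its printed SDs;
the formula as stated is what is implemented, and the two will not agree
on any data.)

Angular velocity is computed by centered differences on the time-domain
angle *before* cycle normalization (differencing the resampled grid would
scale errors with cadence); power is moment × velocity with moment and
angle in a common plantarflexion-positive convention; work is trapezoid
integration of the positive and negative power lobes over stride time.
The exoskeleton torque is divided by body mass and subtracted from the
total (inverse-dynamics) moment to give the biological moment;
contribution shares are ratios of the peaks of the *mean* curves
(matching a "peak total power" reading), and the work share uses positive
work.

**Statistics.** Scalar RMS outcomes get a one-way ANOVA across the six
windows — repeated-measures by default, since the same subjects cross all
conditions; classical Fisher one-way is the comparison mode — with Tukey
HSD post-hocs when the omnibus p < 0.05. Curve outcomes get
one-dimensional SPM with permutation inference instead of random-field
theory: the pointwise F curve is referred to the permutation distribution
of its maximum (labels permuted within subject), the family-wise
threshold is the empirical (1−α) quantile, clusters are maximal
suprathreshold runs with cluster-mass permutation p-values, and all
p-values use the (b+1)/(n_perm+1) convention so they are never zero.
Monte-Carlo calibration (500 null simulations × 200 permutations) puts
the family-wise error at 0.05 ± 0.02. The paired-t sample-size function
scans n against the noncentral-t power function; it reproduces the
standard n = 34 at d = 0.5, α = 0.05, power 0.8, two-tailed. At d = 0.97
the one-tailed minimum is 9 (power at n = 8 is 0.794, just under target),
so published figures of 8 subjects at that effect size are not exactly
reproducible under standard conventions.

## Noise-free reference values

`nominal_decomposition` computes the model-implied device contribution
without noise: the expected extracted envelope is the causal low-pass of
the true envelope (the rectified-carrier scale factor cancels in
calibration), the gain anchors the unpowered stride peak to 7.6 A, and
the resulting torque is decomposed against the moment/angle templates at
nominal cadence using the same curve math as the pipeline.
`nominal_percent_changes` gives the configured end-of-practice envelope
changes. Parameter-recovery tests compare full-pipeline estimates on 12
synthetic subjects against these references: percent changes agree to
within ±3 percentage points and the peak-power share to within ±0.03.

## Numerical choices and degenerate inputs

- Envelope clipped at zero (the low-pass can undershoot after sharp
  drops); NaN input and sub-Nyquist rates are errors, not warnings.
- Strides shorter than 3 samples are skipped with a warning; windows with
  fewer than the requested 30 strides raise, naming the shortfall.
- An all-zero envelope cannot be calibrated (error), and a zero
  Boots-Only reference cannot normalize (error).
- Ties in permutation p-values: (b+1)/(n_perm+1).
- GRF event debouncing: upward crossings closer than 0.4 s are chatter.
- All seeds are explicit; identical configs produce byte-identical
  datasets and reports (timestamps live only in the run manifest, never
  in the report).

## Problem sizes

Default analyses use the full study conditions: 12 subjects × 50 minutes,
EMG at 1000 Hz, mechanics at 100 Hz, 30-stride windows, 300 permutations
for pipeline SPM, 500 simulations × 200 permutations for the family-wise
calibration. The unit-test suite uses compressed sessions (1–3 minutes
per condition with a 0.5-minute adaptation time constant) that preserve
every structural property at a fraction of the cost.

## Known limitations

- No musculoskeletal dynamics: envelopes, moments and angles are
  independent templates, so the generator cannot express biomechanical
  trade-offs (e.g., reduced biological moment when assisted).
- Raw EMG is amplitude-modulated Gaussian noise; spectral changes with
  fatigue or electrode shift are not modeled.
- The affine device-angle model compresses velocity uniformly; real
  cuff-compliance effects are phase-dependent.
- Repeated-measures ANOVA assumes sphericity (no correction applied);
  the permutation SPM makes no such assumption.
- The multi-day arm of the protocol is a configuration hook (timelines
  are arbitrary), not a modeled learning process.
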