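# Methods

`calyxkit` simulates and analyses in vivo recordings from the calyx of
Held–MNTB principal cell synapse: juxtacellular complex waveforms under a
two-noise-burst auditory protocol, whole-cell step and current-clamp
sweeps, paired-pulse Na⁺-current recordings, and confocal-like image
stacks of the axon initial segment (AIS).  Every generator stores its
ground truth, and the test suite's backbone is closure: each analysis
module, run on synthetic data, must recover what was injected.

## The resource-depletion model of short-term depression

Transmission strength in the absence of plasticity is `A`.  One or two
independent depression states `D_k ∈ (0, 1]` multiply it:

    amplitude_i = A · Π_k D_k(t_i⁻)
    D_k ← D_k · (1 − f_k)                        (at each event)
    D_k(t) = 1 − (1 − D_k) · e^(−Δt/τ_k)         (between events)

`f_k` is the depletion fraction (analogous to release probability for the
synaptic signal, or the inactivating channel fraction for spike
signals), `τ_k` the recovery time constant.  With two states the
composition is multiplicative, so single-event recovery is a mixture of
a fast and a slow exponential — the form seen in spike-derivative
recovery at this synapse.  The per-event recursion is exact; a test
verifies it against naive 1 µs Euler integration of `dD/dt = (1 − D)/τ`
to within 0.1%.

Fitting is bounded nonlinear least squares (`scipy.optimize.least_squares`,
TRF) over `{A, f_k, τ_k}` with `f ∈ [0, 0.999]`, `τ ∈ [0.1, 10⁴] ms`,
multi-started from a log grid on τ (ordered pairs for the two-state
model); the smallest residual sum wins, ties broken toward the smaller
fast τ.  Variance explained is `1 − SS_res/SS_tot`; a constant observed
series is returned as the canonical `f = 0` solution with the variance
flagged undefined.  Options: a `soft_l1` loss with `f_scale` near the
per-event noise scale, and a second trimmed pass (`trim_mult`, drop
events whose first-pass residual exceeds that multiple of the robust
residual scale).  Both are used for trace-derived prespike series, whose
measurement errors are heavy-tailed at short inter-event intervals; the
robust estimator was chosen on synthetic validation runs and is
documented below under "known limitations".

Empirical exponential fits (`fit_onset_decay` in units of evoked event
number, `fit_recovery_after_tone` in ms, Na⁺ recovery `1 − e^(−Δt/τ)`)
use `curve_fit` with free offsets (the Na⁺ asymptote is fixed at 1 by
default because amplitudes are relative; a free-asymptote option exists
for noisy data).  Constant series are flagged unidentifiable rather than
fitted.

## Synthetic data: what it emulates and what it does not

**Stimulus protocol.** 200 ms silence, two 400 ms wide-band noise bursts
at 80 dB SPL separated by one of six gaps (40–1280 ms), 4 s sweeps.
Only burst timing is modelled; no acoustics.

**Spike trains.** Inhomogeneous Poisson with a 1 ms absolute refractory
period, realized by thinning.  The rate is the spontaneous rate outside
bursts and `steady + (peak − steady)·e^(−t/τ_adapt)` inside (defaults
26 / 311 / 155 events/s, τ_adapt 30 ms — the onset-to-steady time course
is not constrained by data, and the single exponential with a 30 ms
constant is a stand-in).  Because a dead time removes a fraction
`r·dead` of opportunities, the hazard is compensated
(`h = r/(1 − r·dead)`) so the *observed* rates match the targets; a PSTH
over 500 sweeps recovers the onset peak and steady rate within a few
percent.

**Per-event amplitudes.** The three complex-waveform features carry
independent depletion dynamics.  Defaults are the wild-type group
means: eAP′ two states (f 0.6 @ τ 1.58 ms; f 0.05 @ τ 109 ms), prespike
one state (f 0.35 @ τ 3.88 ms), eEPSP′ one state (f 0.161 @ τ 235 ms —
the depletion fraction implies the observed ~5.7-event onset of
depression at burst rates, `τ_onset ≈ −1/ln(1−f)` when little recovery
fits inside an interval).  The mutant-like parameter set lowers the fast
eAP′ constant to 1.32 ms, the prespike constant to 2.53 ms, the eEPSP′
constant to 88 ms and the failure probability to 0.014.  The depletion
fractions themselves are not reported quantities; they were fixed once
at values that reproduce plausible depression depths (spike amplitudes
attenuating to roughly half during sustained firing, EPSPs depressing
strongly at burst rates).  Failures are per-event Bernoulli
(default 0.106) with an optional interval-dependent variant whose
probability rises below ~10 ms.

**Waveform kernels** (parametric, controllable, not biophysical):
prespike = asymmetric biphasic lobe pair (sharp positive Gaussian, σ
0.06 ms, then a shallow slow negative lobe — the slow return keeps the
prespike's recovery flank out of the EPSP derivative, where a symmetric
derivative-of-Gaussian would corrupt eEPSP′ in depressed states); eEPSP
= saturating exponential rise whose initial slope is the injected
eEPSP′, truncated into a decay when the spike takes over; eAP =
sharp-onset spike (exponential upstroke, τ 0.04 ms, into a cusp whose
decay constant is set by the requested halfwidth) followed by a delayed
downward after-wave (α-function, τ 0.8 ms, 35% of the spike peak).  The
after-wave is what makes events overlap at short intervals and is the
reason template subtraction exists.  Default delays and halfwidth follow
the measured complex-waveform statistics (prespike→EPSP 0.33 ms,
EPSP→spike 0.28 ms, halfwidth 0.24 ms).  Traces sum events linearly and
add white Gaussian noise (default 0.05 mV at 50 kHz); no 1/f or line
noise.

**Whole-cell sweeps.** The voltage-clamp step is an ideal single
compartment: peak `step/Rs`, steady state `step/(Rs+Rm)`, relaxation
`τ = Cm·Rs·Rm/(Rs+Rm)`, with EPSC-like transients superposed.  The
current-clamp generator places a fast logistic EPSP whose midpoint (the
derivative maximum) sits exactly at the spike threshold, followed by a
sharp-onset super-Gaussian AP whose width is calibrated numerically so
the rendered width at half of (peak − rest) equals the requested
halfwidth; subthreshold events are α-shaped with per-event peak
depolarizations.  This makes the two threshold estimators and the AP
features exactly checkable.

**Na⁺ paired pulses.** Two 3 ms inward transients (activation ×
inactivation shape, fast deactivation at step end); the second peak is
`first · (1 − e^(−Δt/τ_rec))`, with a constant baseline offset and white
noise.  The amplitude measurement (peak minus a local pre-pulse
baseline, lightly smoothed) stays clear of the first pulse at the
shortest intervals.

**AIS stacks.** A flat-capped cylinder (so the structure's axial extent
equals the ground-truth skeletal length) with a smooth ~20% intensity
variation along its axis (heterogeneous labeling — also what gives the
2×-threshold hysteresis its seeds), blurred by an anisotropic Gaussian
PSF (σ 0.3 µm axial, 0.15 µm lateral) and corrupted by Poisson shot
noise over a uniform background; default voxel spacing 0.1×0.1×0.5 µm,
peak 400 counts over background 20 (SNR ≥ 20).

## Event detection and measurement

Detection clusters local maxima of the boxcar-smoothed (0.1 ms)
derivative above a threshold (default 3 mV/ms).  Within a cluster, shape
identifies the eEPSP rise: a dominant steep peak is the spike upstroke
and the event time is the latest peak 0.12–0.45 ms before it; without a
dominant peak the waveform is subthreshold and the EPSP rise is the last
peak (prespike lobes always come first), double-checked by whether the
trace keeps rising afterwards (an EPSP) or falls into a negative lobe (a
lone prespike, in which case the subthreshold EPSP rise just after it is
located on the raw derivative).  When the EPSP rise itself is below
threshold (deep depression) the event time falls back to a nominal
0.25 ms before the upstroke peak.  Events are suppressed within a 1 ms
refractory period, with a much stronger cluster replacing a weak
neighbour (an isolated prespike otherwise masks its own spike).

Per event: eEPSP′ is the maximum smoothed derivative in a tight window
around the event time (kept tight so the upstroke's leading edge stays
out); the prespike amplitude is peak-to-baseline, the baseline being the
median of 2 ms preceding the prespike window with samples claimed by the
previous event excluded; eAP′, peak and interpolated halfwidth come from
the window up to 1.5 ms after the rise, trimmed at the next event.  An
event is a failure when the maximum post-EPSP derivative stays below
`4×(derivative noise SD) + 1.5×eEPSP′`.  All windows and multipliers are
config knobs (`EventConfig`).

## Template subtraction

Isolated suprathreshold events (no successor within 2.5 ms for the
downward phase, nor within the 8 ms template tail) are sorted into 4–6
quantile subgroups by maximum downward rate; within a group, members
whose RMS distance to the provisional mean exceeds 3× the group median
RMS are discarded in one pass, and the rest averaged.  For each
overlapped event the template closest in downward rate to the *previous*
event is aligned at the previous event's baseline intersection (first
interpolated zero crossing after its spike peak; when the next event
distorts that crossing, the spike peaks are aligned instead), the
alignment refined by a small least-squares search over sub-sample
offsets, amplitude-scaled by least squares over the downward phase, and
subtracted in full from a working copy of the trace — corrections
accumulate along the sweep.  Two regions are bridged by linear
interpolation afterwards because no amplitude-scaled template can null
them: the previous event's own prespike/EPSP (their ratio to the spike
varies with the depression state, unlike the spike-locked after-wave)
and the cusp of the spike peak.  A previous event without a downward
phase (a failure) needs no correction and is flagged so.  Prespike
amplitudes are then re-measured on the corrected trace; only series
whose mean prespike exceeds 0.3 mV enter the recovery analysis.  The
outlier rule and the scaling objective are conventions of this
implementation; the source procedure states neither.

## Intrinsic properties, thresholds, Na⁺ recovery

Resistances: spontaneous events are blanked (±2 ms, linear
interpolation; step transitions protected), repeats averaged;
`R_series = step/peak` (extreme sample within 0.5 ms of onset),
`R_input = step/steady state` (last 20% of the step), `R_membrane`
their difference — an identity that holds exactly.  AP features: resting
potential is the histogram mode; amplitude is peak minus rest; halfwidth
is interpolated at half of that amplitude; the derivative is a smoothed
central difference.  Threshold estimator 1 is the voltage at the last
derivative local maximum before the AP upstroke (the EPSP inflection);
estimator 2 is the most positive subthreshold peak at preceding
intervals > 10 ms (maximum by default, a 99th-percentile variant is
provided because the maximum is noise-sensitive).  Junction-potential
corrections (−11 mV in vivo, −13 mV slice — protocol metadata, never
hard-coded) are applied exactly once and recorded.

## AIS pipeline

Lower threshold: IsoData on the middle plane (`n_z // 2`), iterating
`T ← (mean(≤T) + mean(>T))/2` from the global mean to a 0.5-intensity
tolerance (cross-checked against scikit-image's implementation in a
test).  Upper threshold: 2× the lower.  Hysteresis: 26-connected
components of the lower mask containing at least one voxel above the
upper threshold (verified against a brute-force flood fill).  The
largest component is thinned (`skimage.morphology.skeletonize`) and the
length is the longest geodesic along the skeleton with anisotropic
Euclidean steps (double-sweep Dijkstra; endpoints contribute no
half-voxel padding, so a straight n-voxel rod measures (n−1) steps).
Skeletons with more than two endpoints are flagged branched for review.

## Problem sizes

Parameter-recovery runs use roughly the sizes a single good recording
session would give: ~2000 events (eight 4 s sweeps) for the two-state
eAP′ fits, 30 sweeps (~6400 measured prespikes) for the
template-subtraction recovery, 100 post-burst sweeps for the recovery
fit, 50 sweeps for the onset fit, ~10⁵ spontaneous events for the
failure percentage, and 20 stacks for the AIS mean.

## Known limitations

* Trace-derived eAP′ and eEPSP′ carry a constant multiplicative
  underestimate (a cusp upstroke sampled at 50 kHz) plus additive
  contamination near the noise floor.  The constant factor cancels in
  time-constant fits, but deeply depressed eEPSP′ values (below ~2 mV/ms
  at the default noise) sit on a measurement floor, which flattens onset
  series and biases trace-level recovery constants fast.  The
  parameter-recovery checks for the EPSP quantities therefore operate on
  amplitudes generated directly from the depletion model, which is also
  how the measured series are fitted in practice.
* Prespike measurement at intervals below ~3 ms has heavy-tailed errors
  even after subtraction (~0.2 mV outliers in a few percent of events);
  the robust trimmed fit absorbs them for the wild-type constant
  (3.88 ms), but recovery constants near 2.5 ms approach the resolution
  limit of this waveform/noise combination and are recovered with
  ordering preserved rather than unbiased magnitude.
* The discrete-time derivative of a sub-0.1 ms AP upstroke depends on
  the sample clock; AP dV/dt changes by several percent between 50 and
  100 kHz while amplitude and halfwidth are stable to <1%.
* The spike-train law, the adaptation time course, the failure law at
  long intervals, and all waveform shapes are stand-ins chosen for
  controllability; passing closure tests shows the analysis recovers
  what these generators inject, not that the generators reproduce every
  feature of real recordings (no 1/f noise, no electrode drift, no
  multi-unit contamination, straight unbranched AIS rods).
* No correction for multiple testing is applied anywhere; group
  comparisons report both Student's t and Mann–Whitney U p-values as
  plumbing.
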