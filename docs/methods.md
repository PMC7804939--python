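# Methods

## The circuit model and its assumptions

The model is a threshold-linear (rectified) firing-rate network of three
populations — pyramidal (E), parvalbumin (P) and somatostatin (S) — arranged
on a one-dimensional tonotopic continuum, position `x` in log2-kHz over
`[2, 6]` (best frequencies 4–64 kHz).  It is phenomenological: "activity" is
a population rate, not a membrane potential, and the spatial axis stands for
the cortical tonotopic map, not anatomical distance.  The simplifications it
accepts deliberately are (a) no local heterogeneity — every neuron at a
position is identical, so the model speaks to the global BF-dependence of
direction selectivity, not to cell-to-cell scatter; (b) a non-periodic
domain with hard boundaries, because tonotopy has edges (this breaks
translational symmetry and is itself part of the mechanism — neurons at
different positions integrate over different spatial footprints); (c)
instantaneous rate conversion for E and P and a single slow first-order
filter for S, standing in for the slow recruitment of SOM cells.

Connectivity kernels are Gaussians in octave distance, normalized **on the
discrete grid** so that every row of every operator sums exactly to its
effective weight `W_αβ`; a spatially uniform state is then a fixed point of
the full spatial system whenever it solves the 3-dimensional reduced
equation `r = W F(r) + μ`.  Background drives `μ` are always derived from
target baseline rates by the exact linear calibration `μ = (I − W) r⁰`, so
baselines are specified directly in Hz and nothing is tuned by hand at run
time.

## The shipped parameter set

The original study's numeric parameter tables are not part of the available
text, so the package ships a single control parameter set
(`data/default_isn.yaml`) chosen once to satisfy all the structural
constraints the model is described by:

| constraint | realization |
|---|---|
| inhibition-stabilized regime | `W_EE = 1.6 > 1`: the E-only subsystem is linearly unstable (largest eigenvalue +60 s⁻¹) while the full circuit is stable (−6.7 s⁻¹) |
| broad SOM connectivity, in and out | λ = 2.0 oct for every pair involving S, 0.3 oct for all others |
| slow SOM recruitment | τ_S^r = 150 ms (τ^m = 10 ms for all populations) |
| low pyramidal baseline | r⁰ = (1, 8, 4) Hz, so sweep-evoked suppression drives E and P to the firing threshold |
| feedforward drive to E and P | Amp = (10, 10, 0), σ = 0.3 oct; which populations receive thalamic drive is not constrained by the available text, and thalamocortical input targets pyramidal and PV cells far more strongly than SOM cells |

With these values the control circuit reproduces every qualitative claim the
model is responsible for: network suppression below baseline after the
excitatory transient, DSI > 0 at every included position below 16 kHz (and
< 0 above) at 5, 10, 20 and 40 oct/s, collapse of selectivity under SOM
inactivation / narrowed SOM scales / non-ISN weakening, and preservation
(mild strengthening) under PV inactivation.  Weight magnitudes beyond these
constraints are not meaningful individually; the perturbation experiments are
the sensitivity analysis that matters.

Perturbations follow the study's protocol: photoinactivation scales the
target population's **outgoing** weights by 0.8 and injects a constant
−1.5 current into its dA/dt equation (an option scales incoming weights too,
for sensitivity analyses); the non-ISN variant multiplies all weights and
feedforward amplitudes by β (default 0.2) and recalibrates drives for a
0.1-Hz pyramidal baseline; every perturbed simulation starts from the
perturbed circuit's own steady state.

## Numerics

Integration uses adaptive RK45 at rtol 1e-5 / atol 1e-6, split at the
stimulus gate times so the solver never steps across the drive
discontinuity; trajectories are recorded at 1-ms resolution.  E and P rates
are handled algebraically (`r = A`); a small-τ fallback exists and agrees
with the algebraic path to ~4×10⁻⁴ on the DSI profile at τ = 0.1 ms (the
pointwise rate difference is the genuine lag τ·dr/dt at threshold kinks).
DSI integrals run from stimulus onset to 1 s past offset (configurable) by
trapezoid; rates are back within solver tolerance of baseline well before
that horizon under the shipped parameters.  A half-octave band at each end
of the axis is excluded from all profiles because the hard boundary distorts
the kernels there.  Doubling the grid from 201 to 401 points changes DSI
profiles by < 0.003 absolute.

**Linear-regime null.**  Verifying an exact-zero claim is numerically more
demanding than plotting a profile, so `linear_regime_dsi` defaults to rtol
1e-7 / atol 1e-9, 0.25-ms recording, and a settle horizon scaled by the
measured stability margin (so the slowest linear mode decays to ~1e-7).  The
run is rejected if any rate variable touches zero.  For arbitrary parameter
draws the static network gain onto E can pass through zero along the axis,
making the DSI an ill-conditioned 0/0 there; positions whose integrated
response is below 1% of the integrated feedforward drive are reported as
missing rather than as amplified rounding error — the same logic by which
the experimental statistic is computed only for responsive cells.  Random
re-parameterizations for the null property scale weights and spatial scales
log-uniformly in ×[0.5, 2], rejecting unstable or fully non-responsive
circuits, with a fixed seed.

## Analysis-pipeline conventions

**Significance rules.**  Thresholds are fixed values, baseline mean +
k × SD with moments pooled over all trials' baseline samples (the
trial-average criterion uses the averaged trace's own baseline moments);
comparisons are strict.  "Consecutively for at least 0.5 s" converts to
sample counts by ceiling.  For unit data the per-trial spontaneous rate
(0–200 ms before onset) is subtracted first, and the per-trial criterion is
same-bin coincidence in more than a third of trials, with the trial-averaged
PSTH required to exceed threshold in at least one bin.  A zero-variance
baseline raises an error rather than passing silently.  The 3.3/3.7-SD
thresholds are shipped as preset constants; the ROC derivation that produced
them requires the original tone recordings and is out of scope.

**DSI conventions.**  Negative amplitudes clamp to zero before the ratio
(keeping DSI in [−1, 1]); both-zero is a missing value, not 0.  A cell's DSI
uses only FM rates significant in at least one direction, averaging
amplitudes across included rates per direction.  BF ties break to the lowest
frequency.

**Whole-cell pipeline.**  All analysis runs on polarity-normalized
trial-averaged traces (evoked direction positive).  The suppression
trajectory is an iterative robust smoother: 50-ms moving average over
currently unflagged samples (flagged spans bridged by linear interpolation),
flagging samples > 3 baseline SD above the smooth with each flagged run
extended to the nearest zero-crossings of the deviation — without that
extension the event tails leak into the average and bias charges down by
tens of percent.  The 50-ms window matches the duration scale of tone-evoked
currents.  Event boundaries come from zero-crossings of a 1-ms-smoothed
residual; supra-threshold runs shorter than 0.5 ms are discarded as sampling
noise; events separated by < 2 ms merge.  These rules are an automatic
surrogate for the original manual, blinded onset/offset placement — the one
step of the published procedure that cannot be reproduced algorithmically
verbatim — and are validated against generator ground truth.  The chord for
the charge is anchored on the trajectory values at onset and offset (the
trace's level at the event's foot), which makes the charge exactly invariant
to adding a constant to the trace and immune to single-sample noise at the
endpoints.  Sweep charges include events with onsets up to 50 ms past sound
offset.

**Vocalization pipeline.**  Syllable detection thresholds a 1-ms maximum
envelope at 10 robust noise SDs (MAD-based), refines edges at 5 SDs and adds
15-ms margins.  Spectrograms use a 512-sample Hann window (488-Hz bins at
250 kHz) with hop equal to the preset time resolution — chosen for 5-ms
segment-slope accuracy; the window is configurable.  Pixels per time bin
collapse to a power-weighted centroid frequency before the least-squares
slope of log2(frequency) vs time is fit per 5-ms segment (an
endpoint-difference estimator would be noisier at the same resolution;
residual tails shorter than 5 ms are dropped).  Connected components use
8-connectivity.  In usage summaries, zero-rate segments split evenly between
upward and downward so the two fractions always sum to 1.

## What the synthetic data does and does not emulate

The generators reproduce the statistical structure each pipeline *assumes*:
Gaussian additive noise for continuous signals, Poisson counts for spikes, a
Poisson barrage of biexponential PSCs with rate-modulated suppression for
currents, and exact logarithmic chirps for audio.  They do not emulate
indicator nonlinearity or shot noise in imaging, spike-sorting artifacts,
series-resistance filtering, harmonic stacks or reverberation in audio, or
any cell-to-cell correlation structure.  Passing recovery tests therefore
demonstrates that the pipelines are correct and well-calibrated under their
own assumptions — not that those assumptions hold for any particular rig.

Reference recovery scenarios (fixed once): calcium — 200 cells, peak dF/F
0.4–1.2, true DSI uniform in ±0.8, frame noise SD 0.15 at 30 Hz, ≥5 trials;
the estimator's mean absolute DSI error is ≈0.01 and decreases with trial
count.  Charge — sparse 20-Hz barrage with 4-pA unitary events and 6-pA
instrument noise, 6-trial averages, one compound event at 5× the averaged
baseline SD; median charge error ≈7% and median peak-time error ≈0.3 ms over
100 replicates.  With the dense (300-Hz) barrage the correlated in-window
barrage charge is irreducible (~30% at 5:1 peak SNR), so the dense setting
is used for trajectory/suppression tests and the sparse one for charge
recovery.  Vocal — 30 syllables, rates 5–25 oct/s, 70% upward, 30-dB
amplitude SNR; median segment-rate error ≈0.2 oct/s.

## Known limitations

- The shipped weights are constraint-satisfying, not fitted; quantitative
  curve shapes (peak DSI values, exact rate-dependence) are not comparable
  to any particular dataset.
- The model DSI can exceed the experimental statistic's range when net
  responses are suppression-dominated (the denominator is signed); an
  optional clamp reproduces the experimental convention.
- The whole-cell event boundaries are an automatic surrogate for a manual
  step; an event-table export supports manual override.
- One-dimensional tonotopy cannot express local DSI heterogeneity, layer
  structure, or two-dimensional map geometry.
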