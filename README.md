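# sweepnet

Why do auditory cortical neurons fire selectively for upward versus downward
frequency-modulated (FM) sweeps?  `sweepnet` implements a recurrent-circuit
answer: a three-population inhibition-stabilized network (ISN) model of mouse
primary auditory cortex (A1) in which broadly projecting, slow somatostatin
(SOM) inhibition triggers a travelling "network suppression" that, combined
with a firing-rate threshold, differentially gates recurrent amplification
between sweep directions.  The package bundles the model, its in-silico
perturbation experiments, and the companion analysis pipelines for
experimental data — all with seeded synthetic-data generators so every
pipeline can be validated against known ground truth.

It is written for computational and systems auditory neuroscientists: people
who want to simulate the circuit, re-run the perturbation experiments under
new parameters, or apply the same selectivity statistics to their own
imaging, unit or whole-cell recordings.

## The model

Neurons live on a one-dimensional tonotopic axis `x ∈ [2, 6]` (best frequency
`2^x` kHz, i.e. 4–64 kHz).  Each population α ∈ {E, P, S} (pyramidal, PV,
SOM) carries an input activity `A_α(x, t)`:

    τ_α^m dA_α/dt = −A_α + Σ_β ∫ K_αβ(x, y) F(r_β(y)) dy + b_α(x, t) + μ_α
    τ_α^r dr_α/dt = A_α − r_α                (instantaneous for E and P)
    F(r) = max(r, 0)

with Gaussian connectivity kernels `K_αβ(x, y) = W_αβ e^{−(x−y)²/λ_αβ²}/G(x)`
normalized so the total weight from β onto α is exactly `W_αβ` at every
position.  An FM sweep is a travelling Gaussian drive at signed rate `s`
(oct/s).  Direction selectivity of a model neuron is

    DSI(x) = (∫Δr_E^up dt − ∫Δr_E^down dt) / (∫Δr_E^up dt + ∫Δr_E^down dt),
    Δr_E = F(r_E) − r_E⁰

Analysis pipelines implement the experimental statistics: the clamped
`DSI = (U − D)/(U + D)` with response-significance criteria for two-photon
imaging (3.3 SD, 0.5 s), single units (3.7 SD, same 50-ms bin) and whole-cell
currents (1 SD, half window); suppression-trajectory estimation and
chord-based fast-PSC charge for voltage-clamp traces; and FM-rate extraction
from vocalization audio (syllable detection, spectrogram contour masking,
5-ms segment slopes in log2-frequency).

## A worked example

```bash
python examples/01_dsi_profile.py
```

prints (201-point grid, ±20 oct/s full-range sweeps):

```
BF (kHz)   DSI
     5.7   +0.450
     8.0   +0.302
    11.3   +0.151
    16.0   -0.000
    22.6   -0.151
    32.0   -0.302
    45.3   -0.458

mean |DSI| over included positions: 0.228
```

Low-BF neurons prefer upward sweeps (DSI > 0), high-BF neurons downward, with
a zero crossing at the 16-kHz tonotopic midpoint: each neuron prefers the
direction in which the sweep moves away from its best frequency, because the
sweep approaching from the far side recruits leading SOM-mediated suppression
that silences recurrent amplification.  `examples/02_perturbations.py` shows
the causal structure — partially inactivating SOM cells collapses the mean
|DSI| from 0.23 to 0.0002 while PV inactivation leaves it intact (0.30) — and
`examples/03_linear_null.py` shows that removing the threshold nonlinearity
(raising baselines so no rate ever clips) abolishes selectivity exactly.
The remaining examples exercise the imaging, whole-cell and vocalization
pipelines on synthetic data with known truth.

## Layout

- `src/sweepnet/model.py` — grid, kernels, steady states, perturbations, integrator
- `src/sweepnet/protocols.py` — sweep pairs, DSI profiles, perturbation suite,
  linear-regime null, feedforward-DSI and restricted-sweep experiments
- `src/sweepnet/dsi_metrics.py` — experimental DSI, significance criteria,
  BF, relative-F_cent analysis
- `src/sweepnet/synaptic_charge.py` — whole-cell trajectory/event/charge pipeline
- `src/sweepnet/vocal_fm.py` — vocalization FM-rate extraction
- `src/sweepnet/synth_data.py` — seeded generators with ground truth
- `src/sweepnet/data/default_isn.yaml` — the shipped control parameter set
- `docs/methods.md` — model assumptions, parameter rationale, numerics, limitations
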