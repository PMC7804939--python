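# Control parameter set: inhibition-stabilized three-population circuit on a
# 4-octave tonotopic axis (x in log2-kHz, BF = 2^x kHz).  Rows/columns and
# vectors are ordered (E, P, S) = (pyramidal, PV, SOM); W is indexed
# (postsynaptic, presynaptic).  Chosen to satisfy the stated qualitative
# constraints: E-only subsystem unstable but full circuit stable (ISN), broad
# SOM input and output scales against a single narrow scale for every other
# pair, slow SOM rate filter, low pyramidal baseline so sweep-evoked network
# suppression engages the firing threshold.
grid:
  x_min: 2.0
  x_max: 6.0
  n_points: 401
weights:
  W:
    - [1.6, -1.2, -1.5]
    - [1.5, -1.0, -0.6]
    - [1.2, -0.0, -0.0]
scales:
  lam:
    - [0.3, 0.3, 2.0]
    - [0.3, 0.3, 2.0]
    - [2.0, 2.0, 2.0]
dynamics:
  tau_m_ms: [10.0, 10.0, 10.0]
  tau_r_ms: [0.0, 0.0, 150.0]
  r0_hz: [1.0, 8.0, 4.0]
stimulus:
  amp: [10.0, 10.0, 0.0]
  sigma: [0.3, 0.3, 0.3]
perturbation:
  weight_scale: 0.8
  inact_current: -1.5
  beta: 0.2
  narrow_lambda: 0.3
analysis:
  edge_exclusion_oct: 0.5
  settle_s: 1.0
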