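# Methods

This note documents the models implemented in `memlstm`, the defaults
and why they were chosen, the numerical choices, and what the synthetic
benchmark does and does not establish.

## Memristive device model

A metal–oxide–metal memristor is described by one internal state
`w ∈ [0, 1]`, the filled fraction of the conductive path.  The current
density mixes an ohmic branch through the formed filament with a
Poole–Frenkel branch through the unfilled oxide:

    j = w · u/ρ + (1 − w) · u · exp(B·u − E_b)

State dynamics are threshold-gated, field-assisted ion migration with a
polynomial window:

    dw/dt = +A · exp(−(E_m − α·|u|)) · (1 − (2w−1)^(2p))   for u ≥ u_set
    dw/dt = 0                                              for u_reset < u < u_set
    dw/dt = −A · exp(−(E_m − α·|u|)) · (1 − (2w−1)^(2p))   for u ≤ u_reset

Conventions that the model family leaves open and that we fix here:

* **Threshold inequalities.** Potentiation at and above the positive
  threshold, depression at and below the negative one, a hard dead zone
  in between.  `V_set`/`V_reset` are synonyms of `u_set`/`u_reset`.
* **Field term.** The exponent uses `α·|u|`, so the depression rate also
  grows with drive magnitude (symmetric barrier lowering).
* **Units.** Barrier parameters `E_b`, `E_m` are dimensionless (units of
  thermal energy, as they appear in the exponent); current is in
  arbitrary consistent units because no device area is fixed.  Joule
  self-heating is not modeled.

Defaults (`A = 1e6 s⁻¹, B = 2 V⁻¹, α = 5 V⁻¹, ρ = 1, E_b = 10,
E_m = 20, p = 5, u_set = +1 V, u_reset = −1 V`) are a documented
reference set producing a pinched hysteresis loop and bistable
switching under a ±1.5 V triangular drive; fitted constants for the
laboratory films this model family describes were never published, so
every value is overridable.

**Numerics.** Explicit Euler with fixed step (default `period/10⁴` for
sweeps); the test suite checks first-order convergence against a 100×
finer reference.  The window function freezes `w` exactly at 0 and 1,
so the integrator clamps the state to `[1e−3, 1 − 1e−3]` to keep
devices switchable — the standard window-function workaround.  Triangle
drives snap voltages below `1e−12·amplitude` to exactly zero so the
pinched-hysteresis identity `j(0) = 0` holds exactly in recorded traces.

## Crossbar encoding

Signed weights cannot live in a single conductance.  Each entry is a
differential pair, `ΔW = G_pos − G_neg`.  Weights are scaled by
`s = (g_max − g_min)/max(1, max|W|)` — the scale is stored on the array
and inverted at the sense stage, keeping the full conductance dynamic
range for any weight magnitude — and split symmetrically about the mid
conductance (balanced wear; exactly invertible).  Because the scale
adapts to `max|W|`, finite weights can never overflow the representable
range; the range error is reserved for non-finite entries.

Nonidealities modeled: uniform quantization to `levels` values (default
256, i.e. 8-bit programming; worst-case read-back error is one grid
step in conductance, `max(1, max|W|)/(levels−1)` in weight units),
multiplicative Gaussian programming noise `G ← G(1+ε)`,
`ε ~ N(0, σ²)`, and stuck devices.  Line resistance, sneak paths and
ADC/DAC stages are out of scope; the VMM is the ideal-wire, ideal-sense
current sum, which equals `read_weights(xbar)ᵀ·v`.

## Forecasting network

Input projection (scalar → feature space), two stacked LSTM layers,
linear output head.  The published description of this architecture
family states a 100-dimensional feature space but not the LSTM hidden
size; we treat them as independent configuration values with equal
defaults (100).  One gate equation in common notation writes the output
gate as a function of `h_t` itself, which is circular; the standard
form with `h_{t−1}` is implemented, matching the recurrence of the
other three gates.

Training is full BPTT on the MSE loss.  Unstated hyperparameters were
fixed once: Adam (lr 1e−3, β = 0.9/0.999), batch 64, max 500 epochs,
early stopping with patience 10 on a chronological validation tail (the
last 10% of training windows, never test data), uniform ±1/√fan-in
initialization, global gradient-norm clipping at 5.  Training is
bit-reproducible for a fixed seed (single-threaded numpy).

**Memristive inference** is programmed-after-training: the network is
trained digitally, each weight matrix is programmed once onto a
crossbar (transposed, so driving the rows with the activation vector
yields `W·x`), and forward passes route every matrix product through
the arrays while biases and the sigmoid/tanh stages stay digital,
mirroring a mixed-signal design.  In-the-loop analog training is a
non-goal.

## Preprocessing and evaluation

* Gaussian filter: σ = 2 samples by default (the smoothing scale is a
  free choice; 16 ms at 8 ms sampling suppresses sample-to-sample noise
  without flattening 100 ms-scale transients), kernel truncated at 4σ,
  reflect padding.
* Split: chronological, train = first ⌊0.8·N⌋ samples.
* Normalization: mean/SD fitted on the training segment only and applied
  to all segments — fitting on everything would leak test statistics.
  In multi-subject designs each recording is normalized with its own
  statistics (per-recording, configurable).
* Windows: stride-1, L = 20 past samples, next sample as target;
  N samples yield exactly N − L pairs.
* Multistep: autoregressive rollout.  RMSE-vs-step evaluates horizon
  s over every test window whose horizon-s target exists.
* Events: two-sided exceedance `|x − mean| > 5·SD` (LFP spikes can be
  negative-going), computed on the evaluated segment itself.  Contiguous
  supra-threshold runs collapse to their extremum; in pipeline
  evaluation, runs separated by ≤ 10 samples are merged, because a
  single transient superposed on background can dip briefly below
  threshold mid-course and would otherwise double-count.  Predicted
  events are extracted from the forecast series with the same rule —
  the forecast series sets its own threshold statistics, which makes
  the criterion robust to a uniform amplitude shrinkage of the
  forecasts.  Matching is greedy, one-to-one, in index order, within
  ±5 samples (40 ms, the five-step horizon); precision and recall are
  reported on the 0–100 scale.  An empty prediction set scores
  precision 100 by convention (no false alarms; switchable).

## Synthetic LFP generator

The generator produces the minimal signal the analysis pipeline needs:

* **Background:** stationary AR(2), coefficients (1.3, −0.4),
  innovation SD 0.34 (background SD ≈ 1), plus a 7 Hz theta sinusoid of
  amplitude 0.3 — hippocampal/entorhinal recordings are theta-rich.
* **Events:** biexponential transients (rise 48 ms, decay 96 ms) at
  Poisson times (default 0.1 Hz, minimum separation 1 s), peak deviation
  8 background-SD.  Two constraints fixed these defaults: the peak must
  clear the 5-SD criterion *of the composed signal*, whose variance the
  events themselves inflate — bounding rate × amplitude² × width — and
  the onset must be visible 40 ms before the peak for short-horizon
  event prediction to be possible at all, requiring a rise time longer
  than the horizon.
* **Anchoring and ground truth.** Each transient's amplitude is set so
  the composed signal attains the target deviation at the injection
  peak; a guarantee pass then raises any peak left within 5% of the
  realized 5-SD threshold to 1.1× threshold (rarely triggered, small).
  The recorded ground-truth index is the *realized* extremum of the
  composed event — background riding on the flat decay can shift the
  actual peak by a few samples, and the realized peak is what any
  amplitude criterion sees.  Together these make every labeled event
  recoverable by the 5-SD detector by construction.
* **Cohorts:** per-subject sub-seeds derive deterministically from the
  master seed (`SeedSequence.spawn`); innovation SD, theta amplitude
  and event rate are jittered uniformly by ±20%, theta frequency by
  ±1 Hz.

What the generator does **not** emulate: realistic LFP spectra (1/f
background, ripples), event-morphology diversity, nonstationarity,
artifacts, or ictal dynamics.  Passing results on this benchmark show
the pipeline is correct and that the architecture can learn and
anticipate stereotyped supra-threshold transients; they do not
establish performance on animal recordings, where event precursors are
weaker and more variable.

## Problem sizes used in tests and the acceptance script

The shipped experiments use a 120 s recording at 8 ms sampling
(15 000 samples, 11 980 training windows), a hidden/feature size of 48,
25 training epochs (batch 128, patience 6), and a held-out 240 s
recording for event scoring — sizes chosen so a full run completes in a
few minutes on one CPU while leaving the conclusions unchanged; larger
networks (the 100-unit default) train the same way, just longer.  Event
scoring uses the longer held-out recording because the 24 s test tail
of a single 120 s signal contains only a handful of events, too few for
stable precision/recall.

## Known limitations

* The LSTM is numpy-based and single-threaded; it is sized for method
  research, not for long-recording production training.
* The memristor parameter set is a reference choice, not a fit to a
  specific film; device-to-device statistics are not modeled.
* EDF export uses a minimal in-package 16-bit encoder (single channel);
  reading goes through `mne` and is format-complete.
* Event matching assumes point events; duration-aware scoring (overlap
  of event intervals) is not implemented.
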