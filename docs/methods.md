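# Methods

## Scope and model

`neurotouch` reimplements, in software, a digital tactile sensory system in
which populations of artificial first-order afferents encode force signals as
spike trains and a machine-learning readout decodes them.  Two afferent
classes are modelled.  SA-I afferents (Merkel-type) respond to the absolute
force and fire throughout a sustained indentation, with rate increasing in
force; FA-I afferents (Meissner-type) respond to force *change* and fire
during the onset and offset ramps only.  Both are built from one of four
discrete-time spiking models — Izhikevich (`izh`), linearized Izhikevich
(`lizh`), quadratic integrate-and-fire (`qif`) and linearized QIF (`lqif`) —
stepped by the explicit Euler rule with h = 0.0078125 ms (2⁻⁷ ms, exactly
representable in binary and in the hardware register format).

The SA-I drive enters inside the h-multiplied bracket as `C·I[n]`; the FA-I
drive is the first difference `C·(I[n+1] − I[n])` added outside the bracket.
The input `I` is the digitized force signal; all physical scaling is absorbed
by the per-model coupling constants, so `I` is treated as dimensionless
(force in mN maps 1:1 unless the optional 10-bit ADC stage is enabled).

### Parameters

Simulation defaults (`NeuronParams.for_model`): a = 0.02 /ms, b = 0.2,
c = −65 mV, d = 8 mV, k₁ = 0.75, k₂ = 20, M₁ = 1, M₂ = 0.0625,
v_peak = 30 mV, v_reset = 0 mV, and input weights
(C_SA, C_FA) = (20, 960) for `izh`, (24, 960) for `lizh`,
(0.015625, 0.5) for `qif`, (1, 40) for `lqif`.  The *improved* L-QIF used by
the population (`NeuronParams.improved_lqif`) is deliberately retuned so all
coefficients are powers of two: M₂ = 0.25, C₄₁ = 0.5, C₄₂ = 16 — every
multiplier of that circuit is realizable as a logical shifter.

Initial conditions are not part of the printed discrete equations; the
package starts the two-variable models at the reset point (v = c, u = b·c)
and the one-variable models at v = v_reset, these being the only
distinguished points of each model.  A "spike" is a reset event; the stored
voltage trace holds v_peak at the spike step (the plotted event marker)
while the internal state continues from the reset value, so no returned
voltage ever exceeds v_peak.

## Fixed-point semantics

The digital circuits solve every state variable in a signed 32-bit register:
1 sign bit, 13 integer bits, 18 fractional bits (range ±8192, resolution
2⁻¹⁸).  The emulation commits to the following concrete semantics, chosen to
match common DSP-slice behaviour and documented so every bit is reproducible:

* quantization of inputs and constants: round to nearest, half away from
  zero, saturating at the register bounds;
* multiplication: full double-width product, truncated back to the register
  grid by an arithmetic right shift (floor, toward −∞) — one reduction per
  multiply, mirroring a single shared register width per signal;
* addition/subtraction: saturating; every saturation increments a
  diagnostics counter (wrap-around would fabricate spikes and is never
  allowed silently);
* shifter path: multiplication by ±2^k as an arithmetic shift; a negative
  coefficient negates the operand *before* the shift, which makes the
  shifter bit-identical to the truncating multiplier for every input (the
  improved L-QIF coefficients are all positive, but the identity is kept
  exact in general);
* the per-step operation order is fixed and identical across the scalar
  reference implementation and the compiled batch kernels; tests assert
  bit-for-bit agreement between the two.

A wide 1+15+48-bit format serves as a near-float oracle: with 48 fractional
bits a single fixed-point step tracks the float64 step to < 1e-9 over random
in-range states, confirming that the arithmetic pipeline (not the register
precision) is faithful.

## Stimuli and the synthetic experiments

All stimuli are piecewise-linear ramp–plateau–ramp ("trapezoid") force
episodes, exact on grid points with no smoothing.

**Reference characterization.**  The 100-ms single-afferent characterization
uses a plateau-dominated trapezoid (10 ms rise, 80 ms hold, 10 ms fall).
The plateau amplitude is the one quantity the characterization leaves
unstated, so it is recovered by calibration: bisection on the amplitude
until the anchor model's SA-I spike count over 100 ms equals its reference
average rate.  Spike counts are monotone non-decreasing in amplitude, so
bisection is sound, and the procedure is fully deterministic.  One amplitude
is calibrated per model family — the Izhikevich model anchors the
two-variable family (760 Hz target) and QIF anchors the one-variable family
(880 Hz) — after which the linearized variants are genuine, non-circular
consistency checks.  At the Izh-anchored amplitude (≈13.01), L-Izh
reproduces its reference rate of 840 Hz exactly.

A single *shared* amplitude across all four models is not possible: with the
printed coupling constants the QIF input weight (C₃₁ = 2⁻⁶) is 64× weaker
than the L-QIF weight (C₄₁ = 1), so the amplitudes required to reach the
reference rates differ per model (≈13 for Izh/L-Izh, ≈139 for QIF, ≈25 for
L-QIF).  Even within the one-variable family, the QIF-anchored amplitude
drives L-QIF to ≈4120 Hz rather than 780 Hz.  The package therefore
reproduces the Izh-family rates and the QIF anchor, and reports the L-QIF
discrepancy rather than hiding it behind a per-model calibration that would
be trivially circular.

**Grid scenarios.**  The 3×3 sensor grid is indexed row-major S1..S9.  A
scenario is a sequence of touch episodes, each pressing one, two or three
sensors with randomized amplitudes (10–40 mN), ramp durations (0.5–2 s),
holds (1–3 s) and gaps.  The default eight-episode sequence pins the first
two episodes to the documented demonstration timing (S1 from 4 s: 2 s rise,
3.5 s hold, 1 s fall; S3+S5 from 14 s: 3 s rise, 2 s hold, 1 s fall, more
force on S3).

**Haptic grasp experiment.**  Five sensors (one per finger), 27 afferents
each → 135 units (50 SA-I + 85 FA-I) running the improved L-QIF in
fixed-point shift arithmetic.  Three objects of strictly increasing grip
force — defaults 25/50/100 mN, a factor-2 spacing in the mid-range of the
afferents' dynamic range — are grasped with 3, 4 or 5 fingers (engaged
fingers always starting from the thumb, sensors 0..k−1), 20 repetitions per
cell: 180 labelled trials of 4 s with a fixed 3-s hold.  The grasp ramps are
0.5 s up and 0.5 s down (the trial length minus the fixed hold, split
evenly; the source experiment does not state them).  The object force is
shared equally among engaged fingers and perturbed per finger by
multiplicative lognormal noise with coefficient of variation 0.2 (the
default "moderate" noise level); per-afferent gain jitter (lognormal,
cv = 0.05) desynchronizes units within a subpopulation.  Optional background
activity is modelled as Poisson-timed rectangular current pulses (default
off; 1 Hz in the raster demo).

What the generator does *not* emulate: FSR transduction nonlinearity and
hysteresis, skin viscoelasticity, sensor cross-talk, human grip-force
variability structure (within-trial drift, finger correlations), and
electrical noise.  Passing decoder tests therefore show that the *pipeline*
recovers object identity from rate-coded spike counts under controlled
noise, not that real glove recordings would reach the same accuracies.

## Decoder

Features are per-afferent spike counts over the full 4-s trial
(FR = spikes/Δt).  Per afferent type (SA-I, FA-I, both) and per finger
condition, trials are decoded under stratified 5-fold cross-validation;
each fold trains on 80% and tests on the held-out 20%, which realizes the
80/20 split and the 5-fold protocol simultaneously.  Within each training
fold, features are z-scored (zero-variance features dropped with a warning —
disengaged fingers produce structurally zero columns), projected onto the
first three principal components (signs fixed by a
largest-loading-positive convention, so the decomposition is deterministic),
and classified by majority vote among the k = 5 Euclidean-nearest training
trials.  Vote ties fall to the tied class with the smallest mean neighbour
distance, then lexicographically — fully deterministic.  A
nearest-class-mean rule is available as an alternative classifier
(`classifier="class-mean"`), reflecting an alternative reading of the
original decoding description.  Scaling and PCA are never fitted on test
folds.  Accuracy is reported as mean ± SD over folds in a 3×3 table.

## Numerical and implementation choices

* Long population runs use numba-compiled kernels that mirror the scalar
  reference simulators operation for operation; unit tests assert
  bit-identity on both arithmetic paths.  Population kernels skip voltage
  trace storage (spike times only).
* Per-unit randomness (gain jitter, noise pulses) derives from
  `SeedSequence(seed, unit_index)`, so results are independent of execution
  order and any unit subset is reproducible in isolation.
* FA afferents consume a one-sample lookahead `I[n+1]`; the final sample
  reuses the last value so the terminal difference is zero (no spurious
  terminal spike).
* Spike times are reported as `(step index) · h` with 1-based update
  indices; they are exact multiples of h and all file round trips are
  lossless at double precision.
* Problem sizes: the characterization runs are 12 800 steps (100 ms); the
  decoder is exercised on the full 180-trial haptic set, and the
  force-noise sweep (cv ∈ {0, 0.1, 0.3, 0.6}) uses 6 repetitions per cell
  (54 trials per level), which is ample to resolve the degradation trend.

## Known limitations

* **FA-I plateau residual.**  The printed discrete dynamics of the
  one-variable models leave a residual membrane value in (0, v_peak) at the
  end of the onset ramp.  QIF (`v²` growth) and L-QIF (`M₂·|v|` growth) have
  no restoring force below threshold, so this residual drifts upward and
  fires exactly one delayed spike in the middle of the plateau, after which
  the membrane sits at v_reset = 0 and is silent for good.  This is a
  property of the equations, not of the implementation: it appears
  identically in float and Q13.18 arithmetic.  The two-variable models relax
  to a stable subthreshold rest and show no plateau spikes.  Strict
  "FA silent on the plateau" therefore holds only up to this single residual
  event for QIF/L-QIF.
* **Offset responses.**  With a clean (noise-free) force signal, FA-I
  offset-phase spikes are scarce: the difference drive is negative during
  the offset ramp.  The offset-versus-onset asymmetry (slower offset ramp →
  fewer offset spikes) holds, but rich offset bursts seen on real sensors
  likely involve sensor dynamics that the generator does not model.
* **Absolute accuracies of the haptic decoder** depend on the chosen object
  forces and noise levels; only the qualitative claims (high accuracy at
  moderate noise, chance level under label permutation, monotone degradation
  with force noise) are meaningful, and only those are asserted.
* Continuous-time integration, adaptive steps, SA-II/FA-II afferents,
  conductance-based models, and hardware resource/power modelling are out of
  scope.
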