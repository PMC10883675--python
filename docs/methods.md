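# Methods

This note documents the model implemented by `cortiphos`, its
assumptions, the numerical and design choices that were genuinely open,
what the synthetic-data generators emulate, and the package's known
limitations.

## Model overview and assumptions

The simulator treats each electrode independently (unless an interaction
mode is enabled) and factors the stimulation-to-percept pathway into
four stages: geometry (where and how large a phosphene is), dynamics
(how strongly tissue is activated over time), perception (whether and
how brightly the phosphene appears), and rendering. The phosphene
percept is assumed round, white, and punctate; multi-phosphene percepts
sum linearly.

### Visuotopic map

The wedge-dipole map is implemented in its *normalized* form
`w = k·log(b(z′+a)/(a(z′+b)))` so that the fovea maps exactly to the
cortical origin and the printed analytic inverse is an exact inverse.
The un-normalized complex-log form differs only by the additive constant
`k·log(a/b)`, which cancels in the magnification; normalizing makes the
forward/inverse pair self-consistent, which the test suite checks to
1e-6 relative over a dense grid. The magnification formula is verified
against the numerical derivative of the forward map along the horizontal
meridian (1e-4 relative).

Hemisphere handedness: cortical coordinates are kept in a canonical
per-hemisphere frame (real part ≥ 0, fovea → periphery, identical for
both hemispheres); handedness is applied when converting to visual-field
Cartesian coordinates, mirroring right-hemisphere phosphenes into the
left hemifield. The electrode CSV records the hemisphere explicitly, so
no information is lost by this convention.

Admissible domain: cortical points are rejected (not clamped) when the
inverse map hits the dipole singularity (`|e^{w/k} − b/a| < 1e-9`) or
returns an azimuth outside `|θ| ≤ π/2`; grid layouts report the
offending electrode indices. There is no established convention for
clamping electrodes beyond the represented hemifield, and silent
clamping would corrupt downstream geometry.

### Units and the activation scale

All internal quantities are SI (amperes, seconds, hertz); configuration
files and the CLI accept µA/µs because every published magnitude uses
those units. The activation variable `A` integrates an ampere-valued
effective current, so `A50`, `θ50` and `σ` are ampere-denominated. With
this (inferred — no unit is stated for `A` in the source fits)
convention, the activation reached by a 166 ms/170 µs/300 Hz train at
100–120 µA is of order 3–4·10⁻⁷, below `A50 = 1.06·10⁻⁶`: absolute
brightness at those amplitudes is far below half-maximum, although it
remains strictly monotone in amplitude, pulse width and frequency. All
quantitative guarantees of this package are therefore *structural*
(rectification boundary, sigmoid midpoint, decay constants,
monotonicity, parameter recovery) rather than absolute brightness
values, and the examples report activation alongside brightness.

### Dynamics

The leaky-integrator updates use explicit forward Euler with exactly one
update per frame — deliberately, so a frame corresponds to one
application of the printed difference equations; exact exponential
integration would change the discrete-time behaviour that the
psychometric constants were fitted under. Stability requires
`Δt < τact`, enforced at configuration time (`RunConfig` default
`Δt = 1/30 s`). First-order convergence is verified: halving `Δt`
halves the error against the analytic solution for piecewise-constant
input.

A "166 ms pulse train" is realized as `⌈duration/Δt⌉` consecutive
stimulated frames; the duration scale `d ∈ (0, 1]` (default 1) scales
stimulation that occupies only part of a frame.

The memory trace `B` is subtracted from the amplitude exactly once, in
the effective-current expression, and is never read by the size
computation. Whether `B` should additionally modify the gating
activation is not separately specified anywhere; the implementation
applies the printed equations literally.

### Thresholds and gating

Detection thresholds are drawn once per electrode at session
initialization from `N(θ50, σ²)` and redrawn until positive: with the
default parameters about 9% of raw draws are non-positive, and a
non-positive detection threshold is physically meaningless. The
resulting threshold population is therefore the positive truncation of
the normal; the sampling test compares against the truncated-normal
mean. Thresholds stay fixed for the session; an explicit
`reinitialize_thresholds(seed)` call supports re-randomization between
experiments.

Hard gating (brightness exactly 0 below threshold) is the default, as
the psychometric constants were fitted under a hard detection rule. The
smooth gate (steep sigmoid, default sharpness 1e9 per activation unit)
and the softplus rectifier are opt-in surrogates for gradient-based use
and are documented as deviations from the reference behaviour.

### Detection probability

Averaging the hard gate over threshold draws gives
`P(detect | A) = Φ((A − θ50)/σ)`. At `A = 0` this expression would give
Φ(−θ50/σ) ≈ 0.087, but the mechanism cannot detect without activation
(thresholds are strictly positive), so the implemented probability is
exactly 0 at `A = 0` and the Φ form above zero. Generator and fitter use
the same predictor, so the fits remain internally consistent; the small
discontinuity at 0⁺ lies below any default threshold draw in practice.

### Size

The current-spread diameter is `D = 2√(I/K)` and the size `P = D/M`:
the only dimensionally consistent reading of the current-spread model
(activated radius grows with √(I/K) for an excitability constant in
µA·mm⁻²) and of a size in degrees obtained from millimetres of cortex.
Size uses the raw instantaneous amplitude by default;
`subtract_rheobase=True` switches to the rectified amplitude (the choice
is genuinely open — "instantaneous current" does not say which — and the
default follows the plainest reading).

### Rendering

Gaussian blobs are *peak*-normalized (peak pixel = brightness) rather
than unit-mass: brightness is defined on [0, 1] per phosphene, and mass
normalization would make small foveal phosphenes invisibly dim.
`σ = P/2` encodes "two standard deviations span the size", consistent
with ~95% of the 1-D profile falling within ±2σ (verified at 0.9545
± 0.005). Pixels are square, fixation is at the exact image centre,
azimuth 0 points right, row 0 is the top. Summation is linear; clipping
to [0, 1] after summation is the default (`clip_mode="none"` for
gradient work — whether clipping or soft saturation better matches
perceptual summation of overlapping phosphenes is unresolved, and plain
summation precedes either).

### Interactions

Self-pairs are excluded from both the co-stimulation penalty and the
coactivation leak (index bounds are otherwise ambiguous): a self-term
would add `Iᵢ²` to the penalty and feed an electrode's own current back
to itself, contradicting the neighbour-interaction purpose. "Active"
means strictly positive amplitude on the current frame. The leak kernel
`1/(1+100d²)` decays fast enough that the sum safely runs over all
active electrodes.

### Amplitude quantizer

The hardware-constraint quantizer snaps to `n` uniformly spaced levels
including both endpoints of [0, max] (default 10 levels over 0–128 µA;
only the count and range are prescribed, uniform-with-endpoints is this
package's choice). `smooth_staircase` provides the matching
sum-of-sigmoids surrogate for straight-through gradient estimation.

## Synthetic data generators

The generators draw trial data under the simulator's own forward model:
detection outcomes are Bernoulli with the probability above, brightness
reports are the gated sigmoid plus Gaussian report noise (means clipped
to [0, 1]), strength-duration data follow `Qthr = I0(c + t)` with
optional multiplicative noise. They emulate the *statistical structure*
of psychophysical datasets (per-condition trial counts, binomial
variability, report noise) but not their nuisance structure — no lapse
or guess rates, no attentional drift, no inter-session threshold drift,
no electrode-specific dynamics. Passing parameter-recovery tests
therefore shows the fits are correctly implemented and identifiable at
realistic sample sizes; it does not show the model would fit real
clinical data, which is not distributed and out of scope.

Condition design: the brightness sigmoid is steep (transition width
~1/λ ≈ 5·10⁻⁹ in activation, ~10 µA in amplitude around ~280 µA for the
default train), so a uniform amplitude grid rarely samples the
transition and leaves the slope unidentifiable. `make_brightness_conditions`
and `make_detection_conditions` place amplitudes at evenly spaced
response quantiles by numerically inverting the train-activation map
(bisection), mirroring adaptive placement in psychophysical practice.
Detection fits, whose transition is wide (σ/θ50 ≈ 0.74), recover fine
from a uniform 25–120 µA grid.

Fits use nonlinear least squares on per-condition proportions
(`scipy.optimize.curve_fit`), with R² on predicted vs. observed
proportions as the goodness-of-fit summary, and condition-stratified
k-fold cross-validation (fold R² undefined for single-condition folds;
reported as NaN and excluded from the mean). The strength-duration fit
is ordinary linear least squares (slope = I0, intercept = I0·c); a
slope indistinguishable from zero flags a degenerate (infinite)
chronaxie instead of failing.

## Problem sizes and tolerances

Test and acceptance runs use deliberately desk-scale problems: grids of
9–400 electrodes, 64–512 px windows, detection fits with 20–30
conditions × 500 trials, brightness fits with 15 conditions × 20
repeats, and the 55-train habituation schedule run without rendering
(the dynamics are per-electrode and cheap; rasterization dominates
runtime and is skipped where only the state trace is needed). Key
tolerances: map round-trip 1e-6 relative; magnification vs. numerical
derivative 1e-4; steady-state and half-life checks 1% at `Δt = τ/100`;
parameter recovery 10% relative (1% noiseless for the brightness
sigmoid); binomial checks at 3 standard errors.

## Known limitations

* Absolute brightness under the default constants is far below
  half-maximum for realistic intracortical amplitudes (see the
  activation-scale section); relative/structural behaviour is faithful.
* Only rectangular biphasic pulse trains; no alternative pulse shapes.
* No double phosphenes or brightness reduction at very high amplitudes;
  no elongated or complex phosphene shapes (Gabor patches are available
  as an appearance option, not a shape model).
* Alternative retinotopies (mono-/dipole variants, LGN, V2–V4) are an
  interface hook (`VisuotopicModel`), not implementations; likewise the
  alternative size model.
* The implementation is numpy-based; operations are continuous and
  piecewise smooth by construction, but no autograd tensors are
  produced. Porting to a tensor backend is mechanical since the hot
  path is closed-form arithmetic.
* No eye-tracking/gaze-contingent rendering, no encoder/decoder
  networks, no GPU benchmarking.
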