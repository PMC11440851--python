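# Methods

## Problem and scope

A dynamic PET scan produces, per voxel, a time-activity curve (TAC,
Bq/ml per frame).  Kinetic modeling relates tissue TACs to a blood input
function; because the tracer reaches each tissue at a different time, the
transport delay ΔT between the input curve and the tissue curve must be
estimated first.  `tacdelay` estimates ΔT at single-voxel noise levels:
each curve's *onset time* is estimated independently and subtracted,
ΔT = T_tissue − T_input.

All curve arithmetic uses frame mid-times.  The acquisition schedules built
in are the two bolus protocols the package targets: 40×1 s + 5×4 s +
6×10 s + 3×20 s (54 frames, 180 s, "h2o") and 40×1 s + 10×5 s + 15×10 s +
6×60 s (71 frames, 600 s, "fdg").  The time origin is scan start; the bolus
arrives ~12 s later.  Activity is assumed decay-corrected upstream; negative
values (iterative-reconstruction noise) are allowed in inputs.

## Onset estimation on the cumulative curve

The raw voxel TAC is too noisy for direct rise fitting.  Its running
integral suppresses zero-mean noise, so the object fitted is the
frame-weighted cumulative sum

    TACsum[k] = Σ_{i≤k} TAC[i]·(mid[i+1] − mid[i]),

with the last frame weighted by its own duration (the consistent limit for
uniform schedules; the mid-time difference is undefined there).  The
mid-time spacing weight keeps a constant-activity curve an exact ramp across
frame-duration changes.

The fitted model is the antiderivative of a logistic rise,
`Asum(t) = a·b·ln(exp((c−t)/b)+1) + a(t−c)`, evaluated as
`a·b·softplus((t−c)/b)` so the exponential cannot overflow.  Parameters and
bounds: a ∈ [0.1, 2×10⁷] (asymptotic slope, activity·units), b ∈ [0.01, 10] s
(transition tightness), c ∈ [0, 60] s (transition centre).  The onset is
T = c − 3.5·b: the curve departs from baseline *before* the transition
centre, by an amount proportional to the transition width; the shape factor
3.5 is an empirical constant of the method and deliberately not a routine
tuning knob.

Robustness stages, in pipeline order:

1. **Plateau removal.**  An early spurious bolus passage (venous pass in the
   injection arm, scatter spill-in) followed by quiescence produces a step
   then a flat plateau in the summed curve, which would anchor the fit on
   the wrong rise.  Runs of ≥3 consecutive points whose spread is within
   0.1 % of the summed curve's first-two-minute maximum are plateau
   candidates; only the first 120 s are scanned so the late tail is never
   flagged.  Among candidate runs, the last one still followed by a genuine
   rise (curve later exceeds the run level by more than the band) is used,
   so the arterial (second) rise is selected.  Correction zeroes the curve
   through the plateau and subtracts the plateau level (mean of the run)
   from later points, clipping at zero.  One pass only; detection is
   deliberately not iterated.
2. **Fit-range selection.**  The summed curve leaves the straight-line
   asymptote once clearance sets in, so the fit should stop near that point.
   Candidate endpoints are local maxima of the absolute second derivative
   (three-point central differences on the non-uniform mid-time grid,
   adjacent-point comparison, ties to the earlier index), taken in
   descending magnitude, at most 10; a featureless curve falls back to the
   last frame.  Every range starts at frame 0 — after plateau correction the
   prefix is zero, so the start adds no bias.
3. **Bounded fitting.**  Each range is fitted by trust-region least squares
   within the bounds above, initialised at a = final value / range span,
   b = 1 s, c = time of half-maximum.  Optimiser failure is encoded as
   R² = −∞ rather than raised; R² on a constant range (zero total sum of
   squares) is likewise −∞.  Fits that converge onto a bound are kept but
   logged.
4. **Filtering and aggregation.**  A fit is accepted iff R² ≥ 0.8, its onset
   is positive, and the onset precedes the end of its fitted range.  The
   ⌈n/2⌉ accepted fits with highest R² are kept and the component-wise
   median of their (a, b, c) yields the final onset.  Zero accepted fits is
   a soft failure (NaN onset), which the delay-map layer handles.

The input function runs through the identical pipeline, so
`estimate_delay(x, x) == 0` exactly and the systematic part of the fitting
offset partially cancels between tissue and input.

## Comparator estimators

**Cross-correlation.**  Both curves are linearly resampled to a uniform 1 s
grid over their common mid-time support, mean-subtracted, and fully
cross-correlated; the delay is the lag of maximum correlation, restricted to
±120 s.  A constant curve has no defined lag (NaN).

**One-tissue compartment model with delay.**  The tissue model is
dC_T/dt = K1·C_A(t − delay) − k2·C_T, C_T(0) = 0, with K1 in ml/(100 g·min)
(internally /6000 → 1/s at density 1 g/ml) and k2 in 1/min.  The solution is
computed exactly for piecewise-linear inputs by an exponential-integrator
recursion on a 0.1 s grid (implemented as an IIR filter), then
integral-averaged over frames — matching how PET frames accumulate counts —
and compared to the measured frames with mid-time ≤ 180 s ("endtime").  The
model is linear in K1, so K1 is profiled in closed form over a coarse
(delay × k2) grid (−20…+60 s at 0.5 s; 48 log-spaced k2 in 0.01–6 /min),
and the grid optimum is refined by joint bounded least squares over
(K1, k2, delay).  The basis is precomputed once per input function, making
batch fitting cheap.  No blood-volume fraction or dispersion term is
modeled.

## Synthetic validation data

Tissue curves are generated from the same one-tissue model driven by a
parametric bolus input standing in for a measured image-derived input
function: a gamma variate `(τ/αβ)^α·e^{α−τ/β}` (zero before arrival,
peak-normalised) plus a recirculation tail
`f·(1−e^{−τ/αβ})²·e^{−λτ}`.  The water preset uses arrival 12 s, α = 2.5,
β = 4 s, peak 30 kBq/ml, tail fraction f = 0.08 with decay
λ = 0.01 s⁻¹ — a plausible late-washout rate (≈70 s half-life), fixed once.

Generation order: dense (0.1 s) solve at zero delay → dense shift by the
true delay with linear interpolation (zero-filled before the shifted start)
→ integral average onto the frame schedule → multiplicative noise
(each frame × N(1, σ²), independent draws, negatives clipped to 0).  σ = 0.1
emulates a few hundred voxels averaged, σ = 0.4 a single voxel.  Seeds are
derived per grid cell from a base seed and the cell's linear index, so the
whole grid is reproducible and individual cells are independent.

The benchmark grid covers K1 = 1:3.5:350 ml/100g·min (100 values),
k2 = 0.05:0.03:3 /min (99 values under inclusive-by-step semantics),
delay = −10:1:10 s (21), σ = 0:0.1:0.5 (6).  The evaluation harness scores
each estimator by the residual delay (true − estimated; negative means the
method over-estimated the arrival delay), maps it on the (K1, k2) plane,
pools mean ± SD per (method, σ), and histograms residuals in 0.25 s bins
over [−8, +8] s.  The headline run (`scripts/acceptance.py`) uses every 5th
K1 and k2 value (20×20 cells), true delay 0, σ ∈ {0.1, 0.4} — problem sizes
chosen so the full three-method benchmark completes in about two minutes on
one CPU while the grid still spans the full parameter ranges.

What the surrogate does *not* emulate: measured aortic input functions have
a broader foot and a substantially higher equilibrium tail (tens of percent
of peak for freely diffusible tracers) than the gamma-variate preset, and
real voxel noise is spatially and temporally correlated rather than
independent multiplicative.  Consequently the absolute residual-delay means
are input-shape sensitive: the onset algorithm's systematic offset
(≈ −1.6 s at σ = 0.1 here) depends on the relative rise sharpness of tissue
vs input; cross-correlation's mean residual is dominated by
low-k2 accumulating cells whose correlation peak runs to very large lags
when the input tail is low; and a one-tissue fit that shares its forward
model with the generator recovers delays nearly unbiasedly.  Relative
statements — noise robustness of the onset method, the strong k2-dependence
and peak-seeking bias of cross-correlation, the noise sensitivity of the
compartment fit — transfer; absolute means on real data do not follow from
these simulations.

## Delay maps

`voxelwise_delay_map` estimates a delay per voxel of a 4D (x, y, z, frame)
volume inside a body mask.  Voxels whose estimate fails are retried on the
mean TAC of their 5×5×5 neighbourhood (truncated at volume borders,
restricted to the body mask); voxels failing both passes carry NaN and are
flagged.  Per-voxel work is pure, so results are independent of processing
order and of the joblib chunking; fallback, failed and direct-success
counts partition the mask exactly.  NIfTI output copies the reference
header geometry and stores float32 with NaN for failures.

## Numerical choices and edge cases

- Degenerate TACs (all zero, <5 frames) fail softly with NaN onsets.
- Plateau band fraction, window, minimum run length, number of fit ranges,
  R² threshold, bounds and shape factor are all exposed via `OnsetConfig`
  (dotted-key JSON for the CLI).
- TAC tables round-trip exactly (`float_precision="round_trip"` on read).
- Second-derivative peak ties break to the earlier index; equal-R² fits
  keep their endpoint order under the stable sort.
- The exponential-integrator coefficients switch to their k2 → 0 series
  below κ = 10⁻⁸ to avoid cancellation; k2 = 0 reduces exactly to the
  trapezoid cumulative integral.

## Known limitations

- Bolus injections only; slow-infusion protocols violate the single-rise
  model assumption.
- No dispersion correction of the input function, no dual-input (hepatic)
  or two-tissue models, no motion handling.
- The 0.1 % plateau band can absorb the first ~0.1 % of a genuine rise,
  contributing a small late bias to onsets; this is inherent to the
  relative-band design and partially cancelled by the −3.5·b correction.
- Onset failure on the *input* function aborts map generation by design —
  no tissue estimate is meaningful without it.
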