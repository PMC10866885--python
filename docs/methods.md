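# Methods

This note documents the models, conventions and numerical choices behind
rtkquant, and what the synthetic-data generators do and do not emulate.

## Single-cell membrane quantification

**Measurement model.** ROI intensities are integrated (summed) pixel
values; membership follows the pixel-centre rule (a pixel belongs to a
polygon iff its centre lies inside or on the boundary), with 0-based pixel
coordinates throughout. The membrane intensity is the exact difference
`I_m = I_ROI1 − I_ROI2`; because both ROIs are integrated over the same
image, everything interior to ROI2 cancels pixel-by-pixel and `I_m`
isolates the peripheral (membrane) ring. Background is supplied as a mean
per-pixel intensity (from untransfected cells or a cell-free region) and
subtracted as `mean × ROI area`, which is robust to ROI size. Negative
`I_m` values are flagged as noise-dominated, kept in raw tables, and
excluded only from ratio analyses where division would be meaningless.

**Binning.** Expression bins are half-open intervals `[k·w, (k+1)·w)`
anchored at zero, `w = 2500` arb. units for the dose–response analysis and
`w = 10000` for normalised-phospho bar summaries. Bins with fewer than
`min_cells = 3` members are dropped and reported; the floor is configurable
because sparse high-expression bins otherwise contribute means of one or
two cells.

**Activation model selection.** The phospho-vs-expression bin means are
fitted with `y = a·x + b` and `y = c·x² + a·x + b` by weighted least
squares and compared with the nested-model F-test at α = 0.05; the
quadratic model is selected only when the test rejects *and* the curvature
c is positive (supra-linear activation). Weights default to
`n_cells / x̄²`: per-cell scatter in fluorescence assays grows roughly in
proportion to the signal (constant CV), and bin occupancies are uneven, so
unweighted OLS makes the F-test anti-conservative — in a 40-seed
calibration study on linear-law populations it selected the quadratic
model ~10–20% of the time, while CV weighting restored the nominal ~5%.
Occupancy-only and unweighted options remain available. Linear fits keep a
free intercept; slope comparisons (`fraction_phosphorylated`) use the
fitted slope only and require a positive reference slope.

**Group statistics.** `ttest_unpaired` is the classical equal-variance
Student's t-test (two-tailed by default), with Welch's correction behind a
flag.

## Confocal FRAP

**Correction (per frame).**
`F_corrected(t) = (F_ROI − F_bg) / (F_total − F_bg)`, then normalisation by
the corrected prebleach reference, taken as the *mean over all prebleach
frames* (averaging ten frames rather than one reduces the variance of the
reference). The ratio cancels exactly any additive background common to
the three traces and any multiplicative fading factor shared by the
above-background spot and whole-cell signals; both invariances are
asserted algebraically in the test suite. A non-positive denominator
raises an error naming the frame.

**Recovery fit.** `f(t) = offset + A(1 − e^(−kt))` with t = 0 at the first
post-bleach frame; free floor `offset`, amplitude bound A ≥ 0, rate bound
k > 0. Initial guesses: offset from the first three frames, plateau from
the last tenth of the trace, rate from the first crossing of half the
recovery span. The optimiser is restarted from three rate guesses
(k₀/5, k₀, 5k₀) and the lowest-SSE solution kept — on noisy traces the
SSE surface has shallow local minima and a single start occasionally lands
in the wrong one. Reported half-times:

* `t_half = 0.69 / k` — the printed convention for the exponential model;
* `t_half_full` — the time at which the *fitted curve* crosses halfway
  between its floor and the full normalised level 1.

The two coincide (up to 0.69 vs ln 2) whenever the fit recovers fully
(offset + A = 1). They diverge on diffusive recoveries: pure 2-D diffusion
refills the spot along a hyperbolic-tailed curve, and a free-amplitude
exponential fitted on a finite window absorbs the unreached tail into a
lowered plateau, so `0.69/k` can undershoot the physical half-recovery
time by up to a factor of two at slow D. The diffusion pipeline therefore
uses `t_half_full`; on exact recovery curves this reproduces the 0.25
coefficient of the confocal relation per grid point within ±0.07, whereas
`0.69/k` drifts from 0.14 to 0.25 across D ∈ {0.01, 0.02, 0.05} µm² s⁻¹.
A fit whose amplitude is indistinguishable from zero (or from the residual
noise) is flagged `no_recovery` instead of raising.

**Effective radius.** The first post-bleach frame, normalised to the mean
prebleach per-pixel intensity, is radially averaged in 1-pixel annuli
around the bleach centre (the commanded centre refined to the centroid of
the bleach-depth map), and `I(r) = 1 − K·e^(−2r²/r_e²)` is fitted with
annulus weights `sqrt(I/n_pixels)` (shot-noise weighting of radial means).
A bleach depth K below 3 standard errors raises a no-bleach error. `r_e`
is expected to be at least the nominal spot radius because diffusion acts
during the bleach; a smaller measured value is flagged, not fatal.

**Diffusion coefficient.** `D_confocal = 0.25 · r_e² / t_half` with the
0.25 constant fixed. Under a Gaussian bleach profile *observed through the
same Gaussian confocal beam profile*, the half-recovery time obeys
`D · t_half = (r_e² + r_n²)/8` exactly, which reduces to `0.25 · r_e²` when
`r_e ≈ r_n`; 0.25 is therefore tied to the confocal observation geometry,
and the simulator's spot trace is emulated accordingly (below). Estimates
are reported in µm² s⁻¹ to 4 decimals; seconds and µm are used internally.

**Oligomer classification.** A sample of per-cell D values is compared to
monomer and dimer control populations with two unpaired two-tailed
Student's t-tests at α = 0.05; the label is the control the sample is
*not* significantly different from, provided the other comparison is
significant; anything else is indeterminate. The benchmark draws control
populations at the reported control means and standard deviations
(monomer 0.033 ± 0.013, dimer 0.021 ± 0.005 µm² s⁻¹; n = 20 per group) and
requires each simulated control population to be labelled as itself with a
significant cross-group comparison; at these effect sizes the cross-group
test has ≈96% power, so the ≥90%-of-seeds check is expected to pass with
margin but can fail for an unlucky seed set.

## Phosphorylation kinetics

Series are max-normalised per replicate (the highest observed intensity
becomes exactly 1). The peak is the argmax of the replicate-averaged
series (optional 3-point median smoothing, off by default; ties resolve to
the earliest index so a post-peak plateau stays fittable). The rise rate
is the OLS slope through the normalised points from t = 0 to the peak; an
all-flat series has rise 0 by convention, while a series that peaks at its
first point raises a no-rise error. The decay is
`I(t) = I_peak · e^(−k_d (t − t_peak))` with the amplitude anchored at the
observed peak — the half-life describes the decay of the highest intensity
observed — fitted to the pooled post-peak points of all replicates. The
result is censored at the window end when k_d is not significantly
positive (one-sided t-test on the fitted rate at α = 0.05) or the model
cannot reach half the peak inside the window; censored results are
reported as `> window_end`. Responses are classified transient when the
uncensored half-life is below half the window (30 min for the default
60-min window) and sustained otherwise, with the boundary classifying as
sustained. The half-window threshold interpolates the observed behaviours
(≈14 min transient; 48 min and censored >60 min sustained) and is
configurable.

## Synthetic-data generators

**FRAP simulator.** N point particles diffuse freely on a periodic square
patch (side 12 µm ≥ 10× the 1.2 µm spot, approximating an unbounded
reservoir), with per-axis step variance 2DΔt. Between recorded frames a
single step of the full frame interval is taken — free-diffusion
increments compose exactly, so substepping there would only cost time —
while the 500 ms bleach is integrated in 50 ms substeps: each substep a
fluorescent particle at distance r from the centre darkens with a
probability that compounds to `K₀·e^(−2r²/r_n²)` for a stationary
particle, so diffusion during the bleach broadens the realised profile.
Photofading darkens survivors at rate λ per frame. Acquisition mirrors a
confocal protocol: 10 prebleach and 120 post-bleach frames at 2 frames/s,
with the first post-bleach frame captured at the end of the bleach. The
three emitted traces are (i) the spot readout — fluorescent particles
weighted by the confocal beam profile `e^(−2r²/r_n²)`, the observation
model under which the 0.25 coefficient holds (a uniform disk integral
recovers measurably faster and would imply a coefficient near 0.4); (ii)
the whole-cell trace — the count of fluorescent particles outside the
nominal spot disk; (iii) an empty background region. All traces carry an
additive background and optional Poisson noise. The default density,
100,000 particles (~700 µm⁻²), represents an overexpressed membrane
receptor; at a few hundred µm⁻² the spot holds so few particles that its
occupancy fluctuations (correlation time ≈ the recovery time itself)
dominate the trace. The rendered first post-bleach frame is a 256² count
histogram normalised to the prebleach mean density. Not emulated: a
realistic PSF, 3-D diffusion, finite closed cells (the patch reservoir is
effectively unbounded over the 60 s window), immobile fractions, and
receptor–receptor interactions — so passing recovery tests demonstrate
correctness of the estimator chain for free 2-D diffusion, not robustness
to binding or geometry effects in real cells.

**Cell-population renderer.** Cells are annular membrane rings (outer
radius 10 px, ring width 3 px) on a square grid with a dimmer cytoplasmic
interior (50% of the membrane signal). Per-cell membrane expression x is
log-normal (ln-mean 9.2, ln-sd 0.8; median ≈ 10⁴ arb. units, range spans
the binning scale), and the phospho signal follows the configured law —
null (constant basal), linear `f·x` (f = 0.3), or quadratic threshold
`c·max(x − x₀, 0)²` (c = 1.5·10⁻⁵, x₀ = 10⁴: silent below a critical
density, supra-linear above) — times a log-normal cell-to-cell scatter
(sd 0.2) representing biological variability, with per-pixel Poisson shot
noise and a flat background of 10 counts/px. ROI pairs are generated with
radii placed in the gap between interior and ring pixel radii so the
interior cancels exactly in `I_m`; a ground-truth table accompanies every
image. Populations default to 100 cells, matching the scale of a
single-condition imaging experiment. Not emulated: irregular cell shapes,
membrane/cytoplasm mislocalisation, focus drift, channel bleed-through.

**Time-course generator.** Piecewise linear rise (slope s, units of the
normalised peak per minute) to a peak at 1/s minutes (so the normalised
peak is exactly 1; a custom peak time rescales the realised slope), then
exponential decay with the configured half-life (infinite = plateau),
multiplicative Gaussian noise (sd 0.05 by default, the replicate-level
scatter typical of densitometry). The sampling grid is a standard
stimulation series (0–60 min, denser early) and always includes the peak
time so noiseless curves round-trip exactly through the fits.

All generators are deterministic given their seed (identical configs give
bit-identical outputs), and every multi-run benchmark derives independent
child seeds from one base seed.

## Benchmark problem sizes

The self-validation studies use D ∈ {0.01, 0.02, 0.05} µm² s⁻¹ × 10 seeds
(30 simulations at the default 10⁵ particles, ≈20 s total), 20 seeds per
activation law for model selection, 20 seeds for oligomer classification
and 10 for kinetics recovery. These sizes put Monte-Carlo error comfortably
below the tolerances being checked while keeping the full suite under a
minute of simulation time.

## Known limitations

* The recovery model is single-component first-order; anomalous diffusion,
  binding/reaction contributions and two-component recoveries are out of
  scope, and on such data the fit will silently average time scales.
* `r_e` estimation assumes an azimuthally symmetric Gaussian bleach; an
  off-centre or saturated (flat-bottomed) profile biases it.
* The transient/sustained boundary at half the window is a reporting
  convention, not an inferred change point.
* The activation F-test assumes the quadratic nests the linear model on
  bin means; it does not distinguish quadratic from other supra-linear
  shapes (e.g. sigmoidal).
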