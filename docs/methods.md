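# Methods

`synaptoscope` turns movies of genetically encoded transmitter sensors
(GRAB-family GPCR sensors, periplasmic-binding-protein sensors such as
iAChSnFR or iGluSnFR) into two kinds of synaptic measurements: the spatial
spread of released transmitter around an isolated release site, and the
vesicle-pool parameters of a release site driven by a prolonged stimulus
train. Because public raw movies for this kind of experiment are not
generally deposited, the package ships a forward simulator with full ground
truth; every estimator is validated as a round trip through that simulator.

## Forward model

Each release site `s` has a readily releasable pool of `N0` vesicles. At
stimulus `k` the number released is drawn Binomial(⌊occupancy⌋, p) and the
pool refills by `R` vesicles per stimulus (deterministic fractional
accumulation, capped at `N0`; Poisson refill is available behind
`stochastic_refill`). A release of `n` vesicles raises ΔF/F at distance `d`
from the site by

    n · q · exp(−d / λ)

where `q` is the quantal ΔF/F (the response to one vesicle at the site
centre) and `λ` the spread length constant. The temporal response is a
causal, peak-normalized difference of exponentials with sensor constants
τ_on and τ_off; all events sum linearly. The isotropic single-exponential
spatial profile is a modeling choice, not a claim about transmitter
diffusion physics: it matches the functional form the spread estimator fits,
which makes model-true recovery testable. Distances are computed to the
sub-pixel site centre, so no grid artifact enters the profile.

Acquisition effects are applied in the physical order: expected
fluorescence `F0·(1 + ΔF/F)` → PSF convolution (per frame, reflective
boundary) → mono-exponential bleaching `exp(−t/τ_bleach)` → rigid drift
(bilinear shift) → Poisson shot noise → additive Gaussian read noise.
`F0` is either uniform or a "speckle" pattern (a smoothed Gaussian random
field applied multiplicatively, default correlation scale 0.3 µm, contrast
0.25) emulating structured tissue autofluorescence; texture is what makes
drift observable to registration, so registration tests use it.

Defaults describe the reference preparation: 0.2 µm pixels, 20 Hz frames,
500 baseline photons/pixel, λ = 0.75 µm, τ_on = 250 ms and τ_off = 700 ms
(GRAB-class acetylcholine-sensor kinetics).

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: time-resolved diffusion (the spatial
profile appears instantaneously), anisotropic or obstructed spread, sensor
saturation and nonlinearity, z-dimension blur and out-of-focus background,
non-rigid tissue motion, dark/flicker sensor states, and correlated camera
noise.

## Resolution arithmetic

The diffraction limit is `Δx = λ_light / (2 NA)`. Detecting `N` photons per
object sharpens the *effective* localization: hardware superresolution
scales as `N^(−1/2)`, computational deconvolution as `N^(−1/4)`, so a 2×
gain costs 4 photons in the first regime and 16 in the second.
`photons_required` inverts these laws (smallest integer `N`). The
theoretical PSF is an isotropic Gaussian with FWHM equal to the Abbe limit —
adequate for the pipeline's purposes; an Airy/Born–Wolf model is a natural
extension point, and on real instruments the empirical PSF should be used
instead.

## PSF estimation from beads

Each frame of a calibration stack is one trial. Spots are local maxima above
20% of the frame maximum; a window of ~6× the expected FWHM is cut around
each, the median of its border ring is subtracted as background, the spot is
centred by intensity-weighted centroid (two refinement passes) applied as a
Fourier shift (band-limited, so centring does not broaden the kernel), and
all spots are averaged, clipped at zero and normalized to unit sum. Spots
closer than one window to a neighbour are excluded as overlapping. FWHM is
measured on the angularly averaged radial profile with cubic interpolation
(linear interpolation biases the FWHM about −2% at σ = 1.5 px). Bead
diameter is reported but not deconvolved out of the estimate; use beads
smaller than half the resolution.

## Preprocessing

*Registration* is rigid translation by phase cross-correlation with 1/50-px
upsampling. Frames and reference are mean-subtracted and Hann-windowed
first — without this the periodic FFT boundary correlates the images at zero
lag and shrinks shift estimates severely. Because physical drift is
continuous, an estimate jumping more than `max_step_px` (default 1.5) from
the previous frame is treated as a correlation false lock and replaced by
the previous drift plus the frame-to-frame displacement. The reference is
the mean of the first 10 frames; the estimated trajectory is therefore
defined up to a constant (the reference's own drift), which is the gauge
used when comparing to ground truth.

*Bleach correction* fits `a·exp(−t/τ) + c` to the mean trace of background
pixels — the half of the field with the smallest relative temporal
modulation `(max−min)/mean`, which excludes release sites *and their
spatial tails* (an intensity-percentile mask does not: exponential
footprints reach dim pixels and masquerade as bleaching). Frames within 5 s
after any stimulus are excluded from the fit so sensor transients cannot
bias τ. The movie is corrected as `(F − c)/exp(−t/τ)`, removing the
constant autofluorescence term along the way. If the fitted total decay over
the movie is under 0.5% the movie is returned untouched; a non-converging
fit falls back to frame-median normalization, flagged in the parameters.
Identifiability note: with a free offset, τ is only well constrained when
the movie spans roughly one decay constant — a 20 s movie cannot pin down
τ = 60 s to 10%, a 60 s calibration movie can.

*ΔF/F* is `(F − F0)/F0` with `F0` the per-pixel mean over a pre-stimulus
window (default: all frames before the first stimulus). Pixels with
non-positive `F0` are masked and excluded downstream.

## Deconvolution

Richardson–Lucy with the Poisson noise model:
`u ← u · [(d / (u ⊛ h)) ⊛ h*]`, reflective padding by one PSF support,
defaults 50 iterations / stop tolerance 1e-4 on the relative change of the
reconvolution RMS residual, optional damping. Non-negativity and total flux
are preserved by construction; flux over the cropped field stays within 1%.
The recorded residual history is computed on the padded domain and cropped
to the original field: the naive "crop, reconvolve with zero boundary"
residual has an irreducible edge artifact for bright extended images, and
the reflection crease region is excluded because reflected data are not the
blur of any object — with this definition the residual is monotone
non-increasing on noiseless consistent input. ΔF/F stacks are deconvolved
as the ratio `1 + ΔF/F` (clipped at 0), which for a spatially uniform
baseline is exactly equivalent to deconvolving the corrected intensity.

On noisy movies the recommended (and pipeline-default-compatible) recipe is:
Gaussian pre-filter (σ 0.5 px), then deconvolve with the *filter-augmented*
PSF (`augment_psf_with_gaussian`): pre-filtering is just extra blur, so
folding it into the kernel removes both in one better-conditioned step
instead of letting RL amplify shot noise.

## Spread length constant

Release sites are local maxima of the temporal-max ΔF/F image above
`max(min_peak_dff, floor + threshold_sd × SD)`, where floor and SD are the
median and 1.4826×MAD of the max image itself. The max of `n` noise frames
has a positive extreme-value floor, so thresholding a max image against a
*per-frame* SD admits dozens of false peaks; measuring the noise on the
statistic being thresholded is what controls them. Centres are refined by
intensity-weighted centroid. Isolated sites are those with no neighbour
within 3 µm (≈ 4 length constants, cross-talk < e⁻⁴). The profile is
pixel-wise maximal ΔF/F (within `[stimulus, stimulus + 3 τ_off]` when an
event window is requested) versus distance to the sub-pixel centre, fitted
by nonlinear least squares to `A·exp(−d/λ)`; the default fit has no offset,
and an offset term is available for noisy data, where the max-image noise
floor acts as a uniform pedestal the offset absorbs. Confidence intervals
come from a pixel-resampling bootstrap (200 draws, 2.5/97.5 percentiles);
they reflect fit noise, not systematic blur bias. On noisy movies, detection
runs on the pre-deconvolution stack (smooth, one peak per site) while the
profile is taken from the deconvolved stack; a σ = 1 frame temporal Gaussian
before the max projection suppresses the extreme-value floor at negligible
cost to the peak (the sensor response is several frames wide).

Under the reference noisy conditions (PSF FWHM 0.5 µm ≈ 0.7 λ, 500
photons), the blurred-profile fit overestimates λ by ~30–35%; after
Richardson–Lucy the estimate is unbiased to a few percent and lands within
±15% of truth in 20/20 seeded runs.

## Vesicle-pool analysis

For a long train the cumulative release versus stimulus number becomes
linear once release is refill-dominated; ordinary least squares on the late
third back-extrapolates to the y-intercept (pool size, ΔF/F units) and
slope (refill per stimulus). A quadratic refit flags residual curvature.
Release probability is the mean of the first 5 release amplitudes divided by
the intercept; the running average of individual amplitudes is also
returned, un-normalized. Quantal size is the first KDE mode of the positive
amplitudes (failures are screened by 3× the noise floor inferred from the
negative amplitudes), or a trimmed minimum (5th percentile). Pool and
refill convert to vesicle units only when a quantal size is available.

Per-stimulus amplitudes come from the ΔF/F trace in two modes. `none` reads
the baseline-referenced increment per inter-stimulus window — correct when
pulses are separated by ≫ τ_off. `kernel` first deconvolves the trace by
the sensor kernel (ridge-regularized Fourier division, ridge 1e-3 of the
peak spectral power) and sums the impulse train per window — required at
16 Hz with τ_off = 700 ms where responses pile up. Regularization smears an
impulse into neighbouring windows, so individual amplitudes carry
noise-level leakage while sums and the cumulative curve are accurate to
< 1%; choose the stimulus rate an integer divisor of the frame rate so
pulses land on frame boundaries.

From a movie, `analyze_pool_movie` localizes the site on the temporal-mean
ΔF/F image — over ~2000 pulses the max image's noise floor exceeds the
per-pulse signal, while sustained release makes the mean the high-SNR
statistic — fits the exponential footprint, and extracts a matched-filter
trace `Σ w·ΔF/F / Σ w²` with `w = exp(−d/λ̂)`, which is the least-squares
amplitude estimate in centre-pixel ΔF/F units and pools the photon budget
of the whole footprint.

Accuracy at the reference train (N0=100, p=0.08, R=0.5, q=0.01, 1920 pulses
at 16 Hz, 500 photons): median intercept −12% of `q·N0` (about half of which
is real physics — the steady-state occupancy `R/p` lowers the asymptote's
intercept to `q(N0 − R/p)` — the rest extraction loss), slope +3% of `q·R`,
release probability −11%, quantal size −17%.

## Numerical choices and conventions

- Axes `(time, row, col)`, 0-based pixels, positions in µm from the centre
  of pixel (0, 0), time in seconds from frame 0, stimulus → frame by
  `floor(t·rate)`.
- Fits use `scipy.optimize.curve_fit` with non-negative bounds on amplitude
  and λ; λ hitting a bound is flagged, non-convergence raises with
  diagnostics.
- Temporal kernels are truncated at 6 τ_off (< 0.3% mass).
- Seeds: every stochastic component derives its stream from the config seed
  through `SeedSequence([seed, stage])`, so outputs are bit-reproducible and
  stages are independently perturbable.
- Degenerate inputs: empty detection lists are valid results; all-zero
  frames are skipped in registration with a warning; masked ΔF/F pixels are
  excluded from profiles and ROIs.

## Problem sizes used by tests and the acceptance script

Spread recovery uses 48×48 px movies, 50 frames, 20 seeds; pool recovery a
24×24 px movie of 3880 frames (1920 pulses), 20 seeds; PSF averaging 8
replicate estimates of 1-spot versus 20-spot stacks. These sizes make the
whole validation run in about a minute and a half on one CPU while keeping
every Monte-Carlo comparison at ≥ 8 replicates; all were chosen as the
smallest instances at which the estimators' asymptotic behaviour is already
visible.

## Known limitations

- The Gaussian theoretical PSF underestimates Airy side lobes; empirical
  PSFs should be preferred for real optics.
- Bootstrap CIs on spread fits do not include deconvolution bias.
- Kernel-mode extraction assumes the sensor kernel is known and linear;
  saturating sensors violate this.
- Registration is rigid translation only; rotation and non-rigid motion are
  out of scope.
- 2-D only: z-blur and out-of-focus light are not modelled or corrected.
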