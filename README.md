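# synaptoscope

Quantitative analysis of fluorescence movies from genetically encoded
neurotransmitter sensors (GRAB-family, iAChSnFR/iGluSnFR-class). From a raw
TIFF stack — or a fully simulated one with known ground truth — the pipeline
runs drift registration, photobleaching correction, ΔF/F computation and
PSF-based Richardson–Lucy deconvolution, then estimates two things a
synaptic physiologist wants from such movies:

1. **Transmitter spread length constant λ** — at an isolated release site,
   the pixel-wise maximal ΔF/F decays with distance `d` from the site as
   `A·exp(−d/λ)`; λ (µm) from a nonlinear least-squares fit measures how far
   released transmitter acts.
2. **Vesicle-pool parameters** — for a prolonged stimulus train, the
   cumulative release versus stimulus number `x` becomes linear late in the
   train; a straight-line fit `f(x) = slope·x + intercept` back-extrapolates
   to the readily releasable pool (intercept, ΔF/F units) and the vesicle
   refill rate (slope, ΔF/F per stimulus). Release probability
   (first releases ÷ pool) and quantal size (first mode of the release-
   amplitude distribution) complete the description.

The optics helpers implement the resolution arithmetic behind the approach:
Abbe limit `λ_light/(2NA)`, with effective resolution improving as `N^(−1/2)`
(hardware superresolution) or `N^(−1/4)` (deconvolution) in the detected
photon count `N` — the quantitative reason deconvolution of a bright,
fast sensor movie can resolve sub-micron transmitter spread on a wide-field
microscope.

Because raw movies of this kind are rarely deposited, the package includes a
first-class forward simulator (binomial vesicle release with pool depletion
and refill, exponential spatial spread, sensor on/off kinetics, PSF blur,
bleaching, drift, Poisson + read noise) and validates every estimator as a
round trip against its ground truth. See `docs/methods.md` for the model
and all numerical choices.

## Worked example

The repository bundles a demo configuration that simulates a single release
site (true λ = 0.75 µm, 500 baseline photons/pixel, PSF FWHM 0.5 µm, 1 px
sinusoidal drift, mild bleaching) and runs the full pipeline on it:

```bash
synaptoscope run --config examples/demo.yaml --seed 1
cat scratch/demo_out/spread_fits.csv
```

```
y_px,x_px,peak_dff,lambda_um,ci_low_um,ci_high_um,amplitude_dff,r2,n_pixels
24.025,22.010,1.097,0.638,0.538,0.716,1.577,0.877,489
```

One isolated site was detected at sub-pixel position (24.03, 22.01) px with
peak ΔF/F ≈ 1.1. The single-exponential fit over the 489 pixels within
2.5 µm gives λ̂ = 0.64 µm (bootstrap 95% CI 0.54–0.72 µm) against a ground
truth of 0.75 µm — a single noisy movie recovers λ to within the ±15% the
estimator achieves across seeds; the bootstrap interval reflects fit noise
only, not residual deconvolution bias. The output directory also contains
the estimated drift trajectory (`drift_estimate.csv`), the bleach fit
(`bleach_fit.json`, τ̂ ≈ 83 s for a simulated 120 s), the simulator's ground
truth, and a provenance log of every stage applied.

The same machinery exposed as a library:

```python
import synaptoscope as st

cfg = st.SimulationConfig(seed=1)                  # one site, λ=0.75 µm
movie, truth = st.simulate_movie(cfg, psf=st.gaussian_psf(0.5, 0.2))
dff = st.compute_dff(st.denoise(movie, "gaussian", 0.5))
dff = st.deconvolve_dff(dff, st.augment_psf_with_gaussian(
    st.gaussian_psf(0.5, 0.2), 0.5))
[(site, fit)] = st.analyze_spread(dff, with_offset=True,
                                  temporal_smooth_frames=1.0)
print(fit.length_constant_um)                      # ≈ 0.75
```

Other entry points: `synaptoscope simulate movie|beads`, `preprocess`,
`psf estimate|theoretical`, `optics abbe|resolution|photons`, `deconvolve`,
`spread`, `pool` (run `synaptoscope --help`).

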