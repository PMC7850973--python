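# End-to-end demo: simulate a single-site sensor movie with drift and
# bleaching, preprocess it, deconvolve, and fit the spread length constant.
# Run with:  synaptoscope run --config examples/demo.yaml --seed 1
output_dir: scratch/demo_out
seed: 1
simulate:
  field_size_px: [48, 48]
  pixel_size_um: 0.2
  frame_rate_hz: 20.0
  n_frames: 60
  stimulus_times_s: [0.5]
  site_positions_um: [[4.7, 4.6]]
  spread_length_um: 0.75
  quantal_dff: 0.2
  pool_size_vesicles: 8
  release_prob: 1.0
  baseline_photons: 500.0
  baseline_pattern: speckle
  bleach_tau_s: 120.0
  drift_trajectory_px: {amplitude_px: 1.0, period_s: 3.0}
psf:
  mode: gaussian
  fwhm_um: 0.5
preprocess:
  register: true
  bleach_model: mono_exp
  denoise_method: gaussian
  denoise_width: 0.5
deconvolve:
  enabled: true
  max_iterations: 50
spread:
  enabled: true
  with_offset: true
  temporal_smooth_frames: 1.0
  n_bootstrap: 100
pool:
  enabled: false
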