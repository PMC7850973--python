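"""Registration, bleach correction, denoising and ΔF/F contracts."""

import numpy as np
import pytest
from scipy import ndimage

import synaptoscope as st
from synaptoscope.core import ConfigurationError


def _speckle_movie(seed=0, drift=None, **kw):
    base = dict(
        field_size_px=(48, 48), pixel_size_um=0.2, frame_rate_hz=20.0,
        n_frames=60, stimulus_times_s=[0.5],
        site_positions_um=[(4.7, 4.6), (6.2, 7.7)],
        spread_length_um=0.75, quantal_dff=0.2, pool_size_vesicles=8,
        release_prob=1.0, baseline_photons=500.0, seed=seed,
        baseline_pattern="speckle", drift_trajectory_px=drift,
    )
    base.update(kw)
    return st.SimulationConfig(**base)


class TestRegistration:
    def test_stationary_movie_zero_shifts(self):
        # static scene: no drift, negligible activity
        cfg = _speckle_movie(seed=1, quantal_dff=1e-9)
        movie, _ = st.simulate_movie(cfg, psf=st.gaussian_psf(0.5, 0.2),
                                     poisson_noise=False)
        _, shifts = st.register_stack(movie)
        assert np.abs(shifts).max() < 0.05

    def test_known_integer_shift_recovered(self):
        cfg = _speckle_movie(seed=2, n_frames=12)
        movie, _ = st.simulate_movie(cfg, psf=st.gaussian_psf(0.5, 0.2),
                                     poisson_noise=False)
        data = movie.data.copy()
        data[-1] = np.roll(np.roll(data[-1], 3, axis=0), -2, axis=1)
        shifted = st.MovieStack(data, movie.pixel_size_um, movie.frame_rate_hz,
                                movie.stimulus_times_s)
        _, shifts = st.register_stack(shifted, max_step_px=10.0)
        assert shifts[-1] == pytest.approx([3.0, -2.0], abs=0.05)

    @pytest.mark.parametrize("seed", [1, 2])
    def test_sinusoidal_drift_rmse(self, seed):
        # amplitude 3 px sinusoid, Poisson noise at 500 photons/px
        cfg = _speckle_movie(
            seed=seed, drift={"amplitude_px": 3.0, "period_s": 3.0}
        )
        movie, truth = st.simulate_movie(cfg, psf=st.gaussian_psf(0.5, 0.2))
        _, shifts = st.register_stack(movie)
        err = shifts - truth.drift_px
        err -= err.mean(axis=0)  # reference frame is a free gauge
        assert float(np.sqrt(np.mean(err**2))) < 0.25

    def test_register_then_inverse_shift_is_identity(self):
        rng = np.random.default_rng(3)
        base = ndimage.gaussian_filter(rng.uniform(100, 200, (64, 64)), 2)
        drift = np.array([[0.0, 0.0], [1.2, -0.8], [2.0, 1.5]])
        frames = [ndimage.shift(base, d, order=1, mode="nearest")
                  for d in drift]
        movie = st.MovieStack(np.stack(frames), 0.2, 10.0)
        registered, shifts = st.register_stack(movie, reference=base)
        # undo the registration using the returned drift
        undone = np.stack([
            ndimage.shift(f, s, order=1, mode="nearest")
            for f, s in zip(registered.data, shifts)
        ])
        interior = (slice(None), slice(4, -4), slice(4, -4))
        rms = np.sqrt(np.mean((undone[interior] - movie.data[interior]) ** 2))
        assert rms / base.mean() < 0.01

    def test_all_zero_frame_skipped_with_warning(self):
        rng = np.random.default_rng(4)
        base = ndimage.gaussian_filter(rng.uniform(100, 200, (32, 32)), 2)
        data = np.stack([base, np.zeros_like(base), base])
        movie = st.MovieStack(data, 0.2, 10.0)
        with pytest.warns(UserWarning, match="all zeros"):
            registered, shifts = st.register_stack(movie)
        np.testing.assert_array_equal(registered.data[1], 0)


class TestBleachCorrection:
    def test_no_bleach_leaves_movie_unchanged(self):
        cfg = _speckle_movie(seed=5, n_frames=100)
        movie, _ = st.simulate_movie(cfg, psf=None, poisson_noise=False)
        corrected, params = st.correct_bleaching(movie)
        np.testing.assert_allclose(corrected.data, movie.data, rtol=1e-3)
        assert params["corrected"] is False

    def test_bleach_tau_recovered_within_10pct(self):
        # a calibration movie spanning about one bleach time constant
        cfg = _speckle_movie(seed=6, n_frames=600, frame_rate_hz=10.0,
                             stimulus_times_s=[2.0], bleach_tau_s=60.0)
        movie, _ = st.simulate_movie(cfg, psf=st.gaussian_psf(0.5, 0.2))
        _, params = st.correct_bleaching(movie)
        assert params["tau_s"] == pytest.approx(60.0, rel=0.10)

    def test_post_correction_background_is_flat(self):
        cfg = _speckle_movie(seed=7, n_frames=200, frame_rate_hz=10.0,
                             stimulus_times_s=[2.0], bleach_tau_s=60.0,
                             quantal_dff=1e-9)
        movie, _ = st.simulate_movie(cfg, psf=None)
        corrected, _ = st.correct_bleaching(movie)
        trace = corrected.data.mean(axis=(1, 2))
        t = corrected.frame_times_s
        rel_slope = np.polyfit(t, trace / trace.mean(), 1)[0] * (t[-1] - t[0])
        assert abs(rel_slope) < 0.005

    def test_constant_offset_autofluorescence_removed(self):
        # F(t) = S·exp(−t/τ) + A with constant autofluorescence A
        t = np.arange(120) / 10.0
        signal = 400.0 * np.exp(-t / 30.0)
        offset = 100.0
        data = (signal + offset)[:, None, None] * np.ones((1, 24, 24))
        movie = st.MovieStack(data, 0.2, 10.0)
        corrected, params = st.correct_bleaching(movie)
        assert params["offset"] == pytest.approx(offset, rel=0.02)
        np.testing.assert_allclose(
            corrected.data[:, 0, 0], 400.0, rtol=0.02
        )

    def test_too_few_frames_rejected(self):
        movie = st.MovieStack(np.ones((5, 8, 8)), 0.2, 10.0)
        with pytest.raises(ConfigurationError):
            st.correct_bleaching(movie)


class TestDenoise:
    def test_none_is_identity(self):
        movie = st.MovieStack(np.random.default_rng(0).poisson(
            500, (10, 16, 16)).astype(float), 0.2, 10.0)
        out = st.denoise(movie, "none", 1.0)
        np.testing.assert_array_equal(out.data, movie.data)

    def test_median_removes_impulse(self):
        data = np.full((3, 16, 16), 100.0)
        data[1, 8, 8] = 10000.0
        movie = st.MovieStack(data, 0.2, 10.0)
        out = st.denoise(movie, "median", 3)
        assert out.data[1, 8, 8] == 100.0

    def test_gaussian_reduces_poisson_variance(self):
        cfg = _speckle_movie(seed=8, baseline_pattern="uniform",
                             quantal_dff=1e-9, n_frames=100)
        movie, _ = st.simulate_movie(cfg, psf=None)
        out = st.denoise(movie, "gaussian", 1.0)
        v0 = movie.data.var(axis=0).mean()
        v1 = out.data.var(axis=0).mean()
        assert v0 / v1 >= 3.0

    def test_unknown_method_rejected(self):
        movie = st.MovieStack(np.ones((3, 8, 8)), 0.2, 10.0)
        with pytest.raises(ConfigurationError):
            st.denoise(movie, "bilateral", 1.0)


class TestDff:
    def test_constant_movie_gives_zero(self):
        movie = st.MovieStack(np.full((20, 8, 8), 321.0), 0.2, 10.0,
                              stimulus_times_s=[1.0])
        dff = st.compute_dff(movie)
        np.testing.assert_array_equal(dff.dff, 0.0)

    def test_doubling_gives_one(self):
        data = np.full((20, 8, 8), 100.0)
        data[15] = 200.0
        movie = st.MovieStack(data, 0.2, 10.0, stimulus_times_s=[1.0])
        dff = st.compute_dff(movie)
        assert dff.dff[15].min() == pytest.approx(1.0)

    def test_noiseless_simulation_roundtrip(self, single_site_config):
        movie, truth = st.simulate_movie(single_site_config, psf=None,
                                         poisson_noise=False)
        dff = st.compute_dff(movie)
        assert np.max(np.abs(dff.dff - truth.ideal_dff)) < 1e-6

    def test_nonpositive_baseline_masked(self):
        data = np.full((20, 8, 8), 100.0)
        data[:10, 2, 2] = 0.0
        movie = st.MovieStack(data, 0.2, 10.0, stimulus_times_s=[1.0])
        with pytest.warns(UserWarning, match="masked"):
            dff = st.compute_dff(movie)
        assert not dff.valid_mask[2, 2]
        assert np.all(dff.dff[:, 2, 2] == 0)

    def test_baseline_must_precede_first_stimulus(self):
        movie = st.MovieStack(np.full((20, 8, 8), 100.0), 0.2, 10.0,
                              stimulus_times_s=[0.5])
        with pytest.raises(ConfigurationError):
            st.compute_dff(movie, baseline_window=(0, 10))


class TestOrderAndMetadata:
    def test_bleach_then_dff_recovers_peaks(self):
        # bleach τ = half the movie length is still correctable within 3%
        cfg = _speckle_movie(seed=9, n_frames=100, frame_rate_hz=20.0,
                             stimulus_times_s=[1.0], bleach_tau_s=2.5,
                             baseline_pattern="uniform")
        movie, truth = st.simulate_movie(cfg, psf=None, poisson_noise=False)
        corrected, _ = st.correct_bleaching(movie)
        dff = st.compute_dff(corrected)
        peak_true = truth.ideal_dff.max()
        peak_est = dff.dff.max()
        assert peak_est == pytest.approx(peak_true, rel=0.03)

    def test_operations_preserve_acquisition_metadata(self, single_site_config):
        movie, _ = st.simulate_movie(single_site_config,
                                     psf=st.gaussian_psf(0.5, 0.2))
        for op in (
            lambda m: st.register_stack(m)[0],
            lambda m: st.correct_bleaching(m)[0],
            lambda m: st.denoise(m, "gaussian", 1.0),
        ):
            out = op(movie)
            assert out.pixel_size_um == movie.pixel_size_um
            assert out.frame_rate_hz == movie.frame_rate_hz
            assert len(out.provenance) == len(movie.provenance) + 1
        dff = st.compute_dff(movie)
        assert dff.pixel_size_um == movie.pixel_size_um
        assert dff.frame_rate_hz == movie.frame_rate_hz
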