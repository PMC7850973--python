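"""Forward-simulator contracts: pool dynamics, rendering, acquisition, beads."""

import numpy as np
import pytest

import synaptoscope as st
from synaptoscope.core import ConfigurationError


def _config(**kw):
    base = dict(
        field_size_px=(32, 32), pixel_size_um=0.2, frame_rate_hz=20.0,
        n_frames=40, stimulus_times_s=[0.5], site_positions_um=[(3.1, 3.1)],
        spread_length_um=0.75, quantal_dff=0.1, pool_size_vesicles=5,
        release_prob=1.0, baseline_photons=500.0, seed=0,
    )
    base.update(kw)
    return st.SimulationConfig(**base)


class TestPoolDynamics:
    def test_full_depletion_in_one_pulse(self):
        cfg = _config(pool_size_vesicles=5, release_prob=1.0,
                      refill_per_stimulus=0.0, n_frames=300,
                      stimulus_times_s=list(np.arange(10) + 0.5))
        released, occupancy = st.simulate_pool_dynamics(cfg)
        assert list(released) == [5] + [0] * 9
        assert released.sum() == 5
        assert occupancy[0] == 5 and np.all(occupancy[1:] == 0)

    def test_zero_release_probability(self):
        cfg = _config(release_prob=0.0, refill_per_stimulus=0.3,
                      n_frames=300, stimulus_times_s=list(np.arange(10) + 0.5))
        released, occupancy = st.simulate_pool_dynamics(cfg)
        assert np.all(released == 0)
        assert np.all(occupancy == cfg.pool_size_vesicles)

    def test_long_train_steady_state_matches_refill(self):
        # long-run balance: mean release ≈ refill per stimulus
        n = 10_000
        cfg = _config(pool_size_vesicles=100, release_prob=0.08,
                      refill_per_stimulus=0.5, frame_rate_hz=100.0,
                      n_frames=n + 100,
                      stimulus_times_s=list(np.arange(n) * 1e-2))
        released, _ = st.simulate_pool_dynamics(cfg)
        steady = released[n // 2:].mean()
        assert steady == pytest.approx(0.5, rel=0.05)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_occupancy_bounds_and_release_feasibility(self, seed):
        cfg = _config(pool_size_vesicles=20, release_prob=0.3,
                      refill_per_stimulus=0.7, frame_rate_hz=100.0,
                      n_frames=600, seed=seed,
                      stimulus_times_s=list(np.arange(500) * 1e-2))
        released, occupancy = st.simulate_pool_dynamics(cfg)
        assert np.all(occupancy >= 0) and np.all(occupancy <= 20)
        assert np.all(released <= np.floor(occupancy[:-1]))

    def test_deterministic_under_seed(self):
        cfg = _config(release_prob=0.4, refill_per_stimulus=0.5,
                      stimulus_times_s=list(np.arange(20) * 0.05),
                      frame_rate_hz=100.0, n_frames=200)
        r1, o1 = st.simulate_pool_dynamics(cfg)
        r2, o2 = st.simulate_pool_dynamics(cfg)
        assert np.array_equal(r1, r2) and np.array_equal(o1, o2)


class TestRenderIdealDff:
    def test_single_vesicle_peak_and_length_constant(self):
        # place the site exactly on a pixel centre
        cfg = _config(site_positions_um=[(3.0, 3.0)], quantal_dff=0.1,
                      pool_size_vesicles=1)
        released = np.array([[1]])
        dff = st.render_ideal_dff(cfg, np.array([[3.0, 3.0]]), released)
        peak = dff[:, 15, 15].max()
        # frame sampling lands within one frame of the kernel peak
        assert peak == pytest.approx(0.1, rel=1e-4)
        # spatial decay at the peak frame is exactly exp(−d/λ)
        yy, xx = np.indices((32, 32))
        d = np.hypot(yy * 0.2 - 3.0, xx * 0.2 - 3.0)
        frame = dff[np.argmax(dff[:, 15, 15])]
        expected = peak * np.exp(-d / 0.75)
        np.testing.assert_allclose(frame, expected, rtol=1e-12, atol=1e-15)

    def test_two_simultaneous_events_double_amplitude(self):
        cfg = _config(site_positions_um=[(3.0, 3.0)])
        one = st.render_ideal_dff(cfg, np.array([[3.0, 3.0]]), np.array([[1]]))
        two = st.render_ideal_dff(cfg, np.array([[3.0, 3.0]]), np.array([[2]]))
        np.testing.assert_allclose(two, 2 * one, rtol=1e-12)

    def test_spatial_conservation_matches_closed_form(self):
        cfg = _config(site_positions_um=[(3.1, 3.15)], pool_size_vesicles=3)
        released, _ = st.simulate_pool_dynamics(cfg)
        dff = st.render_ideal_dff(cfg, np.array([[3.1, 3.15]]),
                                  released.reshape(1, -1))
        yy, xx = np.indices((32, 32))
        d = np.hypot(yy * 0.2 - 3.1, xx * 0.2 - 3.15)
        footsum = np.exp(-d / cfg.spread_length_um).sum()
        t = np.arange(cfg.n_frames) / cfg.frame_rate_hz
        kern = st.sensor_kernel(cfg.sensor_tau_on_ms, cfg.sensor_tau_off_ms,
                                t - 0.5)
        kern[t < 0.5] = 0.0
        expected = released[0] * cfg.quantal_dff * kern * footsum
        got = dff.sum(axis=(1, 2))
        np.testing.assert_allclose(got, expected, rtol=1e-3, atol=1e-12)

    def test_negative_length_constant_rejected(self):
        with pytest.raises(ConfigurationError):
            _config(spread_length_um=-1.0)


class TestSensorKernel:
    def test_causal_peak_normalized(self):
        t = np.linspace(-0.5, 5.0, 2000)
        k = st.sensor_kernel(250.0, 700.0, t)
        assert np.all(k[t < 0] == 0)
        assert k.max() == pytest.approx(1.0, abs=1e-4)

    def test_equal_time_constants_alpha_limit(self):
        t = np.linspace(0, 3.0, 500)
        k = st.sensor_kernel(400.0, 400.0, t)
        assert k.max() == pytest.approx(1.0, abs=1e-4)
        assert np.all(np.isfinite(k))


class TestAcquisition:
    def test_noise_free_identity(self):
        cfg = _config()
        movie, truth = st.simulate_movie(cfg, psf=None, poisson_noise=False)
        expected = 500.0 * (1.0 + truth.ideal_dff)
        np.testing.assert_allclose(movie.data, expected, rtol=1e-12)

    def test_bleach_e_fold_over_movie(self):
        # uniform field, τ_bleach = movie duration → last-frame mean ≈ F0/e
        cfg = _config(field_size_px=(128, 128), quantal_dff=1e-9,
                      n_frames=50, frame_rate_hz=10.0, stimulus_times_s=[4.0],
                      site_positions_um=[(12.0, 12.0)], bleach_tau_s=4.9)
        movie, _ = st.simulate_movie(cfg, psf=None)
        assert movie.data[-1].mean() == pytest.approx(500 * np.exp(-1), rel=0.01)

    def test_poisson_variance_equals_mean(self):
        cfg = _config(quantal_dff=1e-9, n_frames=100)
        movie, _ = st.simulate_movie(cfg, psf=None)
        vm = movie.data.var(axis=0, ddof=1) / movie.data.mean(axis=0)
        assert 0.95 < vm.mean() < 1.05

    def test_negative_expected_photons_rejected(self):
        cfg = _config()
        bad = -1.5 * np.ones((cfg.n_frames, 32, 32))
        with pytest.raises(ConfigurationError):
            st.apply_acquisition_effects(bad, cfg)

    def test_full_simulation_deterministic(self, psf_05um):
        cfg = _config(pixel_size_um=0.2, seed=11)
        m1, t1 = st.simulate_movie(cfg, psf=psf_05um)
        m2, t2 = st.simulate_movie(cfg, psf=psf_05um)
        np.testing.assert_array_equal(m1.data, m2.data)
        np.testing.assert_array_equal(t1.released, t2.released)


class TestBeadStack:
    def test_centered_noiseless_bead_equals_psf(self):
        psf = st.gaussian_psf(0.5, 0.1)
        stack = st.simulate_bead_stack(
            np.array([[24.0, 24.0]]), psf, 1e5, n_trials=1,
            field_size_px=(48, 48), poisson_noise=False,
        )
        img = stack.data[0]
        k = psf.kernel
        h = k.shape[0] // 2
        window = img[24 - h:24 + h + 1, 24 - h:24 + h + 1]
        np.testing.assert_allclose(window / window.sum(), k, atol=1e-12)

    def test_offgrid_bead_centroid_preserved(self):
        psf = st.gaussian_psf(0.5, 0.1)
        stack = st.simulate_bead_stack(
            np.array([[20.3, 24.7]]), psf, 1e6, n_trials=1,
            field_size_px=(48, 48), poisson_noise=False,
        )
        img = stack.data[0]
        yy, xx = np.indices(img.shape)
        cy = (img * yy).sum() / img.sum()
        cx = (img * xx).sum() / img.sum()
        assert abs(cy - 20.3) < 0.1 and abs(cx - 24.7) < 0.1

    def test_spot_count_scales_with_trials(self):
        psf = st.gaussian_psf(0.5, 0.1)
        grid = [(float(y), float(x))
                for y in (20, 60, 100, 140) for x in (20, 60, 100)]
        stack = st.simulate_bead_stack(np.array(grid[:10]), psf, 5000,
                                       n_trials=20, field_size_px=(160, 160))
        est = st.estimate_psf_from_beads(stack, expected_fwhm_px=psf.fwhm_px)
        assert est.n_beads_averaged == 200

    def test_overlapping_beads_flagged(self):
        psf = st.gaussian_psf(0.5, 0.1)
        with pytest.warns(UserWarning, match="separation"):
            stack = st.simulate_bead_stack(
                np.array([[24.0, 24.0], [24.0, 28.0]]), psf, 1e4,
                field_size_px=(48, 48),
            )
        assert stack.provenance[-1]["overlapping"] is True


def test_speckle_baseline_reproducible_and_positive():
    cfg = _config(baseline_pattern="speckle", pattern_contrast=0.25)
    m1, _ = st.simulate_movie(cfg, psf=None, poisson_noise=False)
    m2, _ = st.simulate_movie(cfg, psf=None, poisson_noise=False)
    np.testing.assert_array_equal(m1.data, m2.data)
    assert m1.data.min() > 0
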