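import warnings

import numpy as np
import pytest

import synaptoscope as st


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # tests exercise degenerate inputs on purpose; keep the output readable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def psf_05um():
    """Gaussian PSF, FWHM 0.5 µm at 0.2 µm pixels (diffraction-limited GFP)."""
    return st.gaussian_psf(0.5, 0.2)


@pytest.fixture(scope="session")
def single_site_config():
    """One isolated release site, full first-pulse release, 500 photons."""
    return st.SimulationConfig(
        field_size_px=(48, 48),
        pixel_size_um=0.2,
        frame_rate_hz=20.0,
        n_frames=50,
        stimulus_times_s=[0.5],
        site_positions_um=[(4.7, 4.6)],
        spread_length_um=0.75,
        quantal_dff=0.2,
        pool_size_vesicles=8,
        release_prob=1.0,
        baseline_photons=500.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_site_movie(single_site_config, psf_05um):
    movie, truth = st.simulate_movie(single_site_config, psf=psf_05um,
                                     poisson_noise=False)
    return movie, truth


def make_train_config(seed: int) -> st.SimulationConfig:
    """1920-pulse 16 Hz train at one release site (N0=100, p=0.08, R=0.5,
    q=0.01), sampled at 32 Hz."""
    rate, n_stim, fr, t0 = 16.0, 1920, 32.0, 1.0
    stim = list(t0 + np.arange(n_stim) / rate)
    n_frames = int((t0 + n_stim / rate + 4.0) * fr)
    return st.SimulationConfig(
        field_size_px=(24, 24),
        pixel_size_um=0.2,
        frame_rate_hz=fr,
        n_frames=n_frames,
        stimulus_times_s=stim,
        site_positions_um=[(2.3, 2.25)],
        spread_length_um=0.75,
        quantal_dff=0.01,
        pool_size_vesicles=100,
        release_prob=0.08,
        refill_per_stimulus=0.5,
        baseline_photons=500.0,
        seed=seed,
    )
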