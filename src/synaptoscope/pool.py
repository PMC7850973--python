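"""Vesicle-pool analysis from prolonged stimulus trains.

A long train at moderate rate first depletes the readily releasable pool
(RRP) and then settles into a refill-dominated steady state, so the
cumulative-release curve versus stimulus number becomes linear late in the
train.  Back-extrapolating a straight line fitted to the late points gives
the classic train-based quantal-analysis estimators:

* y-intercept  → RRP size (in ΔF/F units; divide by quantal size for vesicles)
* slope        → vesicle refill rate per stimulus
* mean of the first few individual releases / intercept → release probability
* first mode of the nonzero release-amplitude distribution → quantal size

Per-stimulus release amplitudes are extracted from the ΔF/F trace either as
baseline-referenced increments (``none`` mode, valid when pulses are far
apart relative to the sensor decay) or after temporal deconvolution by the
sensor's response kernel (``kernel`` mode, required when the inter-stimulus
interval is shorter than τ_off).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ConfigurationError, DffStack
from .simulate import sensor_kernel

__all__ = [
    "ReleaseTrain",
    "PoolFit",
    "extract_site_trace",
    "extract_stimulus_responses",
    "analyze_pool_movie",
    "cumulative_release",
    "fit_pool_model",
    "release_probability",
    "estimate_quantal_size",
    "analyze_pool",
]


@dataclass
class ReleaseTrain:
    """Per-stimulus release amplitudes and their running sum."""

    per_stimulus_dff: np.ndarray
    cumulative_dff: np.ndarray
    stimulus_rate_hz: float
    n_clipped: int = 0
    roi_id: str = "roi0"


@dataclass
class PoolFit:
    """Back-extrapolation estimates from the late, refill-dominated phase."""

    pool_estimate_dff: float
    refill_rate_dff_per_stimulus: float
    late_fraction: float
    fit_r_squared: float
    curvature_flag: bool = False
    negative_slope_flag: bool = False
    release_probability: float | None = None
    quantal_size_dff: float | None = None
    pool_vesicles: float | None = None


def extract_site_trace(
    dff: DffStack,
    center_px: tuple[float, float],
    length_constant_um: float,
    max_radius_um: float = 2.0,
) -> np.ndarray:
    """Footprint-weighted (matched-filter) ΔF/F trace at a release site.

    With the site's spatial footprint ``w = exp(−d/λ)``, the least-squares
    estimate of the centre amplitude at each frame is ``Σ w·dff / Σ w²``;
    the returned trace is therefore in centre-pixel ΔF/F units and has a far
    better photon budget than any single pixel.
    """
    cy, cx = center_px
    yy, xx = np.indices(dff.dff.shape[1:])
    d_um = np.hypot(yy - cy, xx - cx) * dff.pixel_size_um
    w = np.where(
        (d_um <= max_radius_um) & dff.valid_mask,
        np.exp(-d_um / length_constant_um),
        0.0,
    )
    norm = float((w**2).sum())
    if norm <= 0:
        raise ConfigurationError("empty ROI footprint")
    return np.tensordot(dff.dff, w, axes=([1, 2], [0, 1])) / norm


def extract_stimulus_responses(
    trace: np.ndarray,
    frame_rate_hz: float,
    stimulus_times_s: np.ndarray,
    kinetics_correction: str = "none",
    sensor_tau_on_ms: float = 250.0,
    sensor_tau_off_ms: float = 700.0,
    ridge: float = 1e-3,
) -> np.ndarray:
    """Per-stimulus release amplitudes from a ΔF/F trace.

    ``none`` mode reads, for each pulse, the increment from the value just
    before the stimulus to the maximum within the inter-stimulus window.
    ``kernel`` mode first deconvolves the trace by the peak-normalized
    sensor kernel (ridge-regularized division in the Fourier domain) and sums
    the resulting impulse train within each inter-stimulus window — the
    amplitudes are then additive even when responses overlap heavily.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ConfigurationError("trace must be 1-D")
    stim_t = np.asarray(stimulus_times_s, dtype=float)
    if stim_t.size == 0:
        raise ConfigurationError("at least one stimulus is required")
    n = trace.size
    stim_f = np.floor(stim_t * frame_rate_hz).astype(int)
    if stim_f.min() < 0 or stim_f.max() >= n:
        raise ConfigurationError("stimulus times outside the trace")
    if stim_t.size > 1:
        isi = np.diff(np.sort(stim_t)).min()
        if isi < sensor_tau_off_ms / 1000.0 and kinetics_correction == "none":
            warnings.warn(
                "inter-stimulus interval is shorter than the sensor decay; "
                "responses overlap — consider kinetics_correction='kernel'",
                stacklevel=2,
            )
    if kinetics_correction == "none":
        return _extract_increments(trace, frame_rate_hz, stim_f,
                                   sensor_tau_off_ms)
    if kinetics_correction == "kernel":
        return _extract_deconvolved(trace, frame_rate_hz, stim_f,
                                    sensor_tau_on_ms, sensor_tau_off_ms, ridge)
    raise ConfigurationError(
        f"unknown kinetics_correction {kinetics_correction!r}"
    )


def _extract_increments(trace, frame_rate_hz, stim_f, tau_off_ms):
    span = max(1, int(math.ceil(3.0 * tau_off_ms / 1000.0 * frame_rate_hz)))
    amps = np.zeros(stim_f.size)
    for k, f in enumerate(stim_f):
        end = stim_f[k + 1] if k + 1 < stim_f.size else min(trace.size, f + span + 1)
        end = min(end, f + span + 1)
        pre = trace[f - 1] if f > 0 else trace[f]
        amps[k] = trace[f:end].max() - pre
    return amps


def _extract_deconvolved(trace, frame_rate_hz, stim_f, tau_on_ms, tau_off_ms,
                         ridge):
    n = trace.size
    # subtract the pre-stimulus baseline so the model trace starts at zero
    f0 = stim_f.min()
    baseline = float(np.median(trace[:f0])) if f0 >= 1 else 0.0
    y = trace - baseline
    support = int(math.ceil(6.0 * tau_off_ms / 1000.0 * frame_rate_hz))
    m = n + support          # zero-pad to kill circular wrap-around
    t = np.arange(m) / frame_rate_hz
    k = sensor_kernel(tau_on_ms, tau_off_ms, t)
    kf = np.fft.rfft(k)
    yf = np.fft.rfft(y, m)
    gain = np.conj(kf) / (np.abs(kf) ** 2 + ridge * np.max(np.abs(kf)) ** 2)
    s = np.fft.irfft(yf * gain, m)[:n]
    # sum the impulse train within each inter-stimulus window
    edges = np.append(stim_f, n)
    amps = np.array([
        s[edges[i]:edges[i + 1]].sum() for i in range(stim_f.size)
    ])
    return amps


def cumulative_release(amplitudes: np.ndarray) -> tuple[np.ndarray, int]:
    """Prefix sums of release amplitudes, clipping negatives at zero.

    Releases are physically nonnegative; negative extracted amplitudes are
    measurement noise and are clipped, with the clipped count returned.
    """
    a = np.asarray(amplitudes, dtype=float)
    n_clipped = int((a < 0).sum())
    return np.cumsum(np.clip(a, 0, None)), n_clipped


def fit_pool_model(
    cumulative: np.ndarray,
    late_fraction: float = 1.0 / 3.0,
    min_late_points: int = 20,
    curvature_tol: float = 0.05,
) -> PoolFit:
    """Straight-line fit to the late phase of the cumulative-release curve.

    Ordinary least squares on the last ``late_fraction`` of points, with
    stimulus number (1-based) as abscissa.  The y-intercept is the pool
    estimate and the slope the refill rate, both in ΔF/F units.  A quadratic
    refit flags residual curvature (late phase not yet refill-dominated).
    """
    c = np.asarray(cumulative, dtype=float)
    if not (0 < late_fraction <= 1):
        raise ConfigurationError("late_fraction must be in (0, 1]")
    k = c.size
    n_late = max(int(math.ceil(late_fraction * k)), 2)
    if n_late < min_late_points:
        raise ConfigurationError(
            f"late phase has {n_late} points; need ≥ {min_late_points}"
        )
    x = np.arange(1, k + 1, dtype=float)[-n_late:]
    y = c[-n_late:]
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    quad = np.polyfit(x, y, 2)
    span = x[-1] - x[0]
    lin_span = abs(slope) * span
    curvature = abs(quad[0]) * span**2
    curvature_flag = lin_span > 0 and curvature / lin_span > curvature_tol
    negative_slope = slope < 0
    if negative_slope:
        warnings.warn("late-phase slope is negative", stacklevel=2)
    return PoolFit(
        pool_estimate_dff=float(intercept),
        refill_rate_dff_per_stimulus=float(slope),
        late_fraction=late_fraction,
        fit_r_squared=r2,
        curvature_flag=bool(curvature_flag),
        negative_slope_flag=bool(negative_slope),
    )


def release_probability(
    amplitudes: np.ndarray,
    pool_fit: PoolFit,
    n_initial: int = 5,
) -> tuple[float, np.ndarray]:
    """Release probability and the running average of individual releases.

    Pr = mean of the first ``n_initial`` (pre-depletion) release amplitudes
    divided by the back-extrapolated pool estimate.  The running average of
    all individual amplitudes is returned alongside, un-normalized.
    """
    a = np.asarray(amplitudes, dtype=float)
    if pool_fit.pool_estimate_dff <= 0:
        raise ConfigurationError(
            "release probability undefined for nonpositive pool estimate"
        )
    m = min(n_initial, a.size)
    pr = float(np.clip(a[:m].mean(), 0, None) / pool_fit.pool_estimate_dff)
    running = np.cumsum(a) / np.arange(1, a.size + 1)
    return pr, running


def _noise_floor(amplitudes: np.ndarray) -> float:
    """Noise SD inferred from the negative amplitudes (pure noise side)."""
    neg = amplitudes[amplitudes < 0]
    if neg.size < 5:
        return 0.0
    return float(np.median(np.abs(neg)) / 0.6745)


def estimate_quantal_size(
    amplitudes: np.ndarray,
    method: str = "histogram_mode",
    min_events: int = 50,
) -> float:
    """Quantal size: the ΔF/F contributed by a single released vesicle.

    ``histogram_mode`` takes the first local maximum of a Gaussian kernel-
    density estimate of the positive amplitudes (amplitudes below 3× the
    noise floor inferred from negative values are treated as failures);
    ``min_positive`` takes the 5th percentile of positive amplitudes, a
    trimmed minimum.
    """
    a = np.asarray(amplitudes, dtype=float)
    floor = 3.0 * _noise_floor(a)
    pos = a[a > max(floor, 0.0)]
    if method == "min_positive":
        if pos.size == 0:
            raise ConfigurationError("no positive amplitudes")
        return float(np.percentile(pos, 5))
    if method != "histogram_mode":
        raise ConfigurationError(f"unknown method {method!r}")
    if pos.size < min_events:
        raise ConfigurationError(
            f"histogram mode needs ≥ {min_events} nonzero amplitudes, "
            f"got {pos.size}"
        )
    if np.ptp(pos) < 1e-12:
        return float(pos[0])
    kde = stats.gaussian_kde(pos)
    grid = np.linspace(0, np.percentile(pos, 99) * 1.2, 2048)
    dens = kde(grid)
    # first interior local maximum
    peaks = np.nonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    )[0] + 1
    if peaks.size == 0:
        return float(grid[np.argmax(dens)])
    return float(grid[peaks[0]])


def analyze_pool_movie(
    dff: DffStack,
    kinetics_correction: str = "kernel",
    sensor_tau_on_ms: float = 250.0,
    sensor_tau_off_ms: float = 700.0,
    late_fraction: float = 1.0 / 3.0,
    n_initial: int = 5,
    quantal_method: str = "histogram_mode",
    roi_radius_um: float = 2.0,
    profile_radius_um: float = 2.5,
    threshold_sd: float = 5.0,
    min_peak_dff: float = 0.02,
) -> tuple[PoolFit, ReleaseTrain]:
    """Train analysis straight from a ΔF/F stack.

    The release site is localized on the temporal-mean ΔF/F image (sustained
    release makes the mean, not the max, the high-SNR statistic over a long
    train), its exponential footprint is fitted, and the matched-filter ROI
    trace is passed to :func:`analyze_pool`.  Analyzes the strongest site.
    """
    from .spread import detect_release_sites, fit_spread_length, spatial_profile

    if not dff.stimulus_times_s:
        raise ConfigurationError("stimulus times are required for pool analysis")
    sites = detect_release_sites(
        dff, threshold_sd=threshold_sd, min_peak_dff=min_peak_dff,
        projection="mean",
    )
    if not sites:
        raise ConfigurationError("no release site detected on the mean image")
    site = sites[0]
    d, v = spatial_profile(dff, site, max_radius_um=profile_radius_um,
                           projection="mean")
    footprint = fit_spread_length(d, v, n_bootstrap=0)
    trace = extract_site_trace(
        dff, site.center_px, footprint.length_constant_um,
        max_radius_um=roi_radius_um,
    )
    return analyze_pool(
        trace, dff.frame_rate_hz, np.asarray(dff.stimulus_times_s),
        kinetics_correction=kinetics_correction,
        sensor_tau_on_ms=sensor_tau_on_ms,
        sensor_tau_off_ms=sensor_tau_off_ms,
        late_fraction=late_fraction, n_initial=n_initial,
        quantal_method=quantal_method,
    )


def analyze_pool(
    trace: np.ndarray,
    frame_rate_hz: float,
    stimulus_times_s: np.ndarray,
    kinetics_correction: str = "kernel",
    sensor_tau_on_ms: float = 250.0,
    sensor_tau_off_ms: float = 700.0,
    late_fraction: float = 1.0 / 3.0,
    n_initial: int = 5,
    quantal_method: str = "histogram_mode",
) -> tuple[PoolFit, ReleaseTrain]:
    """Full train analysis: extraction → cumulative → pool fit → Pr and q."""
    amps = extract_stimulus_responses(
        trace, frame_rate_hz, stimulus_times_s, kinetics_correction,
        sensor_tau_on_ms, sensor_tau_off_ms,
    )
    cum, n_clipped = cumulative_release(amps)
    stim_t = np.asarray(stimulus_times_s, dtype=float)
    rate = (
        1.0 / float(np.median(np.diff(np.sort(stim_t))))
        if stim_t.size > 1 else 0.0
    )
    train = ReleaseTrain(
        per_stimulus_dff=amps, cumulative_dff=cum,
        stimulus_rate_hz=rate, n_clipped=n_clipped,
    )
    fit = fit_pool_model(cum, late_fraction=late_fraction)
    pr, _ = release_probability(amps, fit, n_initial=n_initial)
    fit.release_probability = pr
    try:
        q = estimate_quantal_size(amps, method=quantal_method)
        fit.quantal_size_dff = q
        if q > 0:
            fit.pool_vesicles = fit.pool_estimate_dff / q
    except ConfigurationError:
        fit.quantal_size_dff = None
    return fit, train
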