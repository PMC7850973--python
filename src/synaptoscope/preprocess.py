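"""Movie preprocessing: drift registration, bleach correction, denoise, ΔF/F.

Order of operations for the default pipeline: register → correct bleaching →
ΔF/F.  Deconvolution is applied after ΔF/F by default (a pipeline flag allows
deconvolving raw intensity first instead).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation

from .core import ConfigurationError, DffStack, MovieStack

__all__ = [
    "register_stack",
    "correct_bleaching",
    "denoise",
    "compute_dff",
]


def register_stack(
    movie: MovieStack,
    reference: np.ndarray | str = "mean_first_10",
    upsample_factor: int = 50,
    max_step_px: float = 1.5,
) -> tuple[MovieStack, np.ndarray]:
    """Rigid sub-pixel registration of every frame to a reference image.

    Shifts are estimated by phase cross-correlation with sub-pixel refinement
    and applied by bilinear interpolation.  The default reference is the mean
    of the first 10 frames (drift accumulated there is typically small).
    Returns the registered movie and the estimated per-frame (dy, dx) drift —
    the shift each frame had *acquired*, i.e. the correction applied is its
    negative.  All-zero frames are left in place with a warning.

    Physical drift is continuous, so an estimate that jumps by more than
    ``max_step_px`` from the previous frame's is treated as a correlation
    false lock and replaced by the previous drift plus the frame-to-frame
    displacement.
    """
    data = np.asarray(movie.data, dtype=float)
    if data.shape[0] < 2:
        raise ConfigurationError("registration needs at least 2 frames")
    if isinstance(reference, str):
        if reference != "mean_first_10":
            raise ConfigurationError(f"unknown reference spec {reference!r}")
        ref = data[: min(10, data.shape[0])].mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
    if not np.any(ref):
        raise ConfigurationError("reference image is all zeros")
    # Hann window + mean subtraction suppress the spurious correlation of the
    # periodic FFT boundary, which otherwise shrinks shift estimates
    win = np.outer(np.hanning(data.shape[1]), np.hanning(data.shape[2]))
    ref_w = (ref - ref.mean()) * win
    shifts = np.zeros((data.shape[0], 2))
    out = np.empty_like(data)
    prev_drift: np.ndarray | None = None
    prev_w: np.ndarray | None = None
    for i, frame in enumerate(data):
        if not np.any(frame):
            warnings.warn(f"frame {i} is all zeros; skipped", stacklevel=2)
            out[i] = frame
            prev_w = None
            continue
        frame_w = (frame - frame.mean()) * win
        # phase_cross_correlation returns the shift that maps frame onto ref
        shift, _, _ = phase_cross_correlation(
            ref_w, frame_w,
            upsample_factor=upsample_factor, normalization=None,
        )
        drift = -shift  # drift the frame acquired
        if (prev_drift is not None and prev_w is not None
                and float(np.hypot(*(drift - prev_drift))) > max_step_px):
            # false lock: fall back to previous drift + frame-to-frame step
            step, _, _ = phase_cross_correlation(
                prev_w, frame_w,
                upsample_factor=upsample_factor, normalization=None,
            )
            drift = prev_drift - step
        shifts[i] = drift
        out[i] = ndimage.shift(frame, -drift, order=1, mode="nearest")
        prev_drift = drift
        prev_w = frame_w
    registered = movie.with_data(
        out, "register", reference="mean_first_10"
        if isinstance(reference, str) else "explicit",
        max_shift_px=float(np.abs(shifts).max()),
    )
    return registered, shifts


def _background_trace(data: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    """Mean intensity per frame over background pixels.

    Background pixels default to the half of the field with the smallest
    relative temporal modulation (max−min)/mean.  Pure-background pixels only
    modulate with bleaching (plus noise), identically in relative terms, while
    pixels reached by any release-site footprint modulate more — so ranking by
    modulation excludes the sites and their spatial tails from the bleach fit.
    """
    if mask is None:
        mean = data.mean(axis=0)
        safe = np.where(mean > 0, mean, 1.0)
        modulation = (data.max(axis=0) - data.min(axis=0)) / safe
        mask = modulation <= np.percentile(modulation, 50)
        if not mask.any():
            mask = np.ones(data.shape[1:], dtype=bool)
    return data[:, mask].mean(axis=1)


def _mono_exp(t, a, k, c):
    return a * np.exp(-k * t) + c


def correct_bleaching(
    movie: MovieStack,
    model: str = "mono_exp",
    background_mask: np.ndarray | None = None,
    min_total_decay: float = 0.005,
    response_window_s: float = 5.0,
) -> tuple[MovieStack, dict]:
    """Fit and divide out a mono-exponential photobleaching trend.

    The trend ``a·exp(−t/τ) + c`` is fitted to the mean trace of background
    pixels over stimulus-free epochs (frames within ``response_window_s``
    after any stimulus are excluded so sensor transients cannot masquerade as
    bleaching); the constant ``c`` absorbs autofluorescence and camera
    offset.  The movie is corrected as ``(F − c) / exp(−t/τ)``, which both
    undoes the bleach of the signal and removes the constant background.  If
    the fitted total decay over the movie is below ``min_total_decay`` (no
    measurable bleaching) the movie is returned unchanged with rate ≈ 0.  If
    the fit fails, frame-median normalization is used as a flagged fallback.
    """
    if model not in ("mono_exp", "none"):
        raise ConfigurationError(f"unknown bleach model {model!r}")
    data = np.asarray(movie.data, dtype=float)
    if model == "none":
        return movie.with_data(data.copy(), "bleach_correct", model="none"), {
            "model": "none"
        }
    if data.shape[0] < 10:
        raise ConfigurationError("bleach correction needs ≥ 10 frames")
    t_all = movie.frame_times_s
    trace_all = _background_trace(data, background_mask)
    keep = np.ones(data.shape[0], dtype=bool)
    for t_stim in movie.stimulus_times_s or []:
        keep &= ~((t_all >= t_stim) & (t_all <= t_stim + response_window_s))
    if keep.sum() < 10:
        keep = np.ones(data.shape[0], dtype=bool)
    t = t_all[keep]
    trace = trace_all[keep]
    span = trace[0] - trace[-1]
    p0 = (max(span, 1e-3 * trace.mean()), 1.0 / (t[-1] + 1e-12), min(trace))
    params: dict = {"model": "mono_exp", "fallback": False}
    try:
        popt, _ = optimize.curve_fit(
            _mono_exp, t, trace, p0=p0,
            bounds=([0, 0, 0], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
        a, k, c = popt
        fitted0 = _mono_exp(0.0, a, k, c)
        total_decay = (fitted0 - _mono_exp(t_all[-1], a, k, c)) / max(fitted0, 1e-12)
        params.update(
            amplitude=float(a), rate_per_s=float(k),
            tau_s=float(1.0 / k) if k > 0 else float("inf"),
            offset=float(c), total_decay=float(total_decay),
        )
        if total_decay < min_total_decay:
            params["corrected"] = False
            return movie.with_data(
                data.copy(), "bleach_correct", **params
            ), params
        trend = np.exp(-k * t_all)
        corrected = (data - c) / trend[:, None, None]
        corrected = np.clip(corrected, 0, None)
        params["corrected"] = True
        return movie.with_data(corrected, "bleach_correct", **params), params
    except RuntimeError:
        warnings.warn(
            "bleach fit did not converge; falling back to frame-median "
            "normalization", stacklevel=2,
        )
        med = np.median(data.reshape(data.shape[0], -1), axis=1)
        med = np.where(med > 0, med, 1.0)
        corrected = data * (med[0] / med)[:, None, None]
        params.update(fallback=True, corrected=True)
        return movie.with_data(corrected, "bleach_correct", **params), params


def denoise(movie: MovieStack, method: str = "gaussian", width: float = 1.0
            ) -> MovieStack:
    """Spatial denoising applied frame-by-frame.

    ``gaussian`` uses σ = ``width`` px; ``median`` uses a ``width``-pixel
    square footprint; ``none`` is the identity.
    """
    data = np.asarray(movie.data, dtype=float)
    if method == "none":
        out = data.copy()
    elif method == "gaussian":
        if width >= min(data.shape[1:]):
            raise ConfigurationError("filter width must be < image size")
        out = ndimage.gaussian_filter(data, sigma=(0, width, width))
    elif method == "median":
        w = int(width)
        if w >= min(data.shape[1:]):
            raise ConfigurationError("filter width must be < image size")
        out = ndimage.median_filter(data, size=(1, w, w))
    else:
        raise ConfigurationError(f"unknown denoise method {method!r}")
    return movie.with_data(out, "denoise", method=method, width=width)


def compute_dff(
    movie: MovieStack,
    baseline_window: tuple[int, int] | None = None,
) -> DffStack:
    """ΔF/F = (F − F0)/F0 with F0 the per-pixel mean over a baseline window.

    The default window is every frame strictly before the first stimulus.
    Pixels whose F0 is not positive are masked (dff forced to 0) with a
    warning.
    """
    data = np.asarray(movie.data, dtype=float)
    if baseline_window is None:
        stim = movie.stimulus_frames()
        if stim.size == 0:
            raise ConfigurationError(
                "no stimulus times: supply an explicit baseline_window"
            )
        end = int(stim.min())
        if end < 1:
            raise ConfigurationError(
                "baseline window is empty: first stimulus is in frame 0"
            )
        baseline_window = (0, end)
    lo, hi = baseline_window
    if not (0 <= lo < hi <= data.shape[0]):
        raise ConfigurationError("invalid baseline window")
    stim = movie.stimulus_frames()
    if stim.size and hi > stim.min():
        raise ConfigurationError("baseline window must precede the first stimulus")
    f0 = data[lo:hi].mean(axis=0)
    valid = f0 > 0
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} pixel(s) with nonpositive baseline masked",
            stacklevel=2,
        )
    if f0[valid].size == 0 or f0[valid].mean() <= 0:
        raise ConfigurationError("baseline mean must be positive")
    safe_f0 = np.where(valid, f0, 1.0)
    dff = (data - safe_f0) / safe_f0
    dff[:, ~valid] = 0.0
    return DffStack(
        dff=dff,
        baseline_f0=f0,
        baseline_window=(lo, hi),
        pixel_size_um=movie.pixel_size_um,
        frame_rate_hz=movie.frame_rate_hz,
        stimulus_times_s=movie.stimulus_times_s,
        valid_mask=valid,
        provenance=list(movie.provenance) + [
            {"step": "dff", "baseline_window": [int(lo), int(hi)]}
        ],
    )
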