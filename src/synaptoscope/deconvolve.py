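"""Richardson–Lucy deconvolution with Poisson noise model.

The observed image is modelled as a Poisson realization of the true object
convolved with the PSF.  The Richardson–Lucy iteration

    u ← u · [ (d / (u ⊛ h)) ⊛ h* ]

is the EM algorithm for this model: it preserves non-negativity and total
flux, and monotonically increases the Poisson likelihood.  Boundary handling
uses reflective padding by one PSF support, which keeps flux drift within 1%
on realistic fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import ConfigurationError, DffStack, MovieStack
from .optics import PSFModel

__all__ = [
    "DeconvolutionResult",
    "richardson_lucy",
    "reconvolution_residual",
    "deconvolve_movie",
    "deconvolve_dff",
]

_EPS = 1e-12


@dataclass
class DeconvolutionResult:
    estimate: np.ndarray
    iterations_run: int
    residual_history: list[float] = field(default_factory=list)
    converged: bool = False

    def __post_init__(self) -> None:
        if len(self.residual_history) != self.iterations_run:
            raise ValueError("residual_history length must equal iterations_run")


def _conv_same(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return signal.fftconvolve(image, kernel, mode="same")


def reconvolution_residual(
    estimate: np.ndarray, psf: PSFModel, observed: np.ndarray
) -> float:
    """RMS of (estimate ⊛ psf − observed): the convergence diagnostic."""
    estimate = np.asarray(estimate, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if estimate.shape != observed.shape:
        raise ConfigurationError("estimate and observed shapes must match")
    resid = _conv_same(estimate, psf.kernel) - observed
    return float(np.sqrt(np.mean(resid**2)))


def richardson_lucy(
    image: np.ndarray,
    psf: PSFModel,
    max_iterations: int = 50,
    stop_tol: float = 1e-4,
    damping: float = 0.0,
) -> DeconvolutionResult:
    """Deconvolve a single 2-D frame by Richardson–Lucy iteration.

    Stops at ``max_iterations`` or when the relative change of the
    reconvolution RMS residual falls below ``stop_tol``.  ``damping``
    (0 ≤ damping < 1) exponentially relaxes the multiplicative update, which
    trades convergence speed for noise robustness.
    """
    observed = np.asarray(image, dtype=float)
    if observed.ndim != 2:
        raise ConfigurationError("richardson_lucy expects a single 2-D frame")
    if np.any(~np.isfinite(observed)):
        raise ConfigurationError("input contains NaN or infinite values")
    if observed.min() < -1e-9 * max(observed.max(), 1.0):
        raise ConfigurationError("input must be nonnegative")
    observed = np.clip(observed, 0, None)  # absorb convolution round-off
    if observed.max() == 0:
        return DeconvolutionResult(
            estimate=observed.copy(), iterations_run=0, converged=True
        )
    kernel = psf.kernel
    if kernel.size == 1:
        # delta kernel: RL fixed point is the input itself
        res = reconvolution_residual(observed, psf, observed)
        return DeconvolutionResult(
            estimate=observed.copy(), iterations_run=1,
            residual_history=[res], converged=True,
        )
    pad = kernel.shape[0] // 2
    d = np.pad(observed, pad, mode="reflect")
    u = d.copy()
    mirror = kernel[::-1, ::-1]
    history: list[float] = []
    converged = False
    iters = 0
    for it in range(max_iterations):
        blurred = np.clip(_conv_same(u, kernel), _EPS, None)
        ratio = d / blurred
        update = _conv_same(ratio, mirror)
        if damping > 0:
            update = update**(1.0 - damping)
        u = np.clip(u * update, 0, None)
        iters = it + 1
        # residual over the original image region, reconvolved on the padded
        # domain: free of both the crop-boundary artifact (estimate extends
        # beyond the field) and the reflection crease (pad ring excluded)
        reconv = _conv_same(u, kernel)
        if pad:
            reconv = reconv[pad:-pad, pad:-pad]
        res = float(np.sqrt(np.mean((reconv - observed) ** 2)))
        history.append(res)
        if len(history) >= 2:
            prev = history[-2]
            if prev > 0 and abs(prev - res) / prev < stop_tol:
                converged = True
                break
    estimate = u[pad:-pad, pad:-pad] if pad else u
    return DeconvolutionResult(
        estimate=estimate, iterations_run=iters,
        residual_history=history, converged=converged,
    )


def deconvolve_movie(
    movie: MovieStack,
    psf: PSFModel,
    max_iterations: int = 50,
    stop_tol: float = 1e-4,
    damping: float = 0.0,
) -> tuple[MovieStack, list[DeconvolutionResult]]:
    """Frame-wise Richardson–Lucy deconvolution with a shared PSF.

    The PSF pixel size must match the movie's; no implicit resampling is
    performed.
    """
    if not np.isclose(psf.pixel_size_um, movie.pixel_size_um, rtol=1e-6):
        raise ConfigurationError(
            f"PSF pixel size {psf.pixel_size_um} µm does not match movie "
            f"pixel size {movie.pixel_size_um} µm"
        )
    results = [
        richardson_lucy(frame, psf, max_iterations, stop_tol, damping)
        for frame in np.asarray(movie.data, dtype=float)
    ]
    out = np.stack([r.estimate for r in results])
    deconvolved = movie.with_data(
        out, "deconvolve", algorithm="richardson_lucy",
        max_iterations=max_iterations, stop_tol=stop_tol, damping=damping,
        psf_provenance=psf.provenance, psf_fwhm_um=psf.fwhm_um,
    )
    return deconvolved, results


def deconvolve_dff(
    dff: DffStack,
    psf: PSFModel,
    max_iterations: int = 50,
    stop_tol: float = 1e-4,
    damping: float = 0.0,
) -> DffStack:
    """Deconvolve a ΔF/F stack.

    Richardson–Lucy requires nonnegative input, so the stack is deconvolved
    as the fluorescence ratio ``F/F0 = 1 + ΔF/F`` (clipped at 0) and shifted
    back.  For a spatially uniform baseline this is exactly equivalent to
    deconvolving the corrected intensity movie.
    """
    if not np.isclose(psf.pixel_size_um, dff.pixel_size_um, rtol=1e-6):
        raise ConfigurationError("PSF pixel size does not match ΔF/F stack")
    out = np.empty_like(dff.dff)
    for i, frame in enumerate(dff.dff):
        ratio = np.clip(1.0 + frame, 0, None)
        out[i] = richardson_lucy(
            ratio, psf, max_iterations, stop_tol, damping
        ).estimate - 1.0
    return DffStack(
        dff=out,
        baseline_f0=dff.baseline_f0,
        baseline_window=dff.baseline_window,
        pixel_size_um=dff.pixel_size_um,
        frame_rate_hz=dff.frame_rate_hz,
        stimulus_times_s=dff.stimulus_times_s,
        valid_mask=dff.valid_mask,
        provenance=list(dff.provenance) + [{
            "step": "deconvolve_dff", "algorithm": "richardson_lucy",
            "max_iterations": max_iterations, "stop_tol": stop_tol,
        }],
    )
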