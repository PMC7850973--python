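"""Optical resolution arithmetic and point-spread-function estimation.

The diffraction-limited resolution of a microscope is the Abbe limit
ΔX = λ/(2·n·sinα) ≡ λ/(2·NA).  Collecting more photons improves the
*effective* resolution: hardware superresolution scales as N^(-1/2), while
computational deconvolution scales as N^(-1/4), so a given resolution gain is
far more photon-hungry for deconvolution — the price paid for working with an
ordinary wide-field microscope.

The PSF used for deconvolution can be theoretical (a Gaussian with FWHM set to
the Abbe limit) or empirical, estimated by imaging sub-resolution fluorescent
beads and averaging many background-subtracted, sub-pixel-centred spots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import ConfigurationError, MovieStack

__all__ = [
    "OpticalConfig",
    "PSFModel",
    "abbe_limit",
    "effective_resolution",
    "photons_required",
    "theoretical_psf",
    "estimate_psf_from_beads",
    "radial_symmetrize",
    "kernel_fwhm_px",
]

GAUSSIAN_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # ≈ 2.3548


@dataclass(frozen=True)
class OpticalConfig:
    """Imaging-system parameters.

    Supply either ``numerical_aperture`` directly or the pair
    (``refractive_index``, ``half_angle_deg``), in which case
    NA = n·sin(α).  ``photon_count`` is the number of photons detected per
    resolvable object, which sets the effective resolution.
    """

    wavelength_nm: float
    numerical_aperture: float | None = None
    refractive_index: float | None = None
    half_angle_deg: float | None = None
    photon_count: float = 1.0

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0:
            raise ConfigurationError("wavelength_nm must be > 0")
        have_na = self.numerical_aperture is not None
        have_pair = (
            self.refractive_index is not None and self.half_angle_deg is not None
        )
        if have_na == have_pair:
            raise ConfigurationError(
                "supply exactly one of numerical_aperture or "
                "(refractive_index, half_angle_deg)"
            )
        if have_pair:
            if self.refractive_index < 1:
                raise ConfigurationError("refractive_index must be ≥ 1")
            if not (0 < self.half_angle_deg <= 90):
                raise ConfigurationError("half_angle_deg must be in (0, 90]")
        else:
            if self.numerical_aperture <= 0:
                raise ConfigurationError("numerical_aperture must be > 0")
            if (
                self.refractive_index is not None
                and self.numerical_aperture > self.refractive_index
            ):
                raise ConfigurationError("NA cannot exceed the refractive index")
        if self.photon_count <= 0:
            raise ConfigurationError("photon_count must be > 0")

    @property
    def na(self) -> float:
        if self.numerical_aperture is not None:
            return self.numerical_aperture
        return self.refractive_index * math.sin(math.radians(self.half_angle_deg))


@dataclass
class PSFModel:
    """A 2-D blur kernel, normalized to unit sum, with provenance.

    ``kernel`` has odd side lengths and its global maximum at the centre
    pixel.  ``fwhm_um`` is the full width at half maximum of the radial
    profile.
    """

    kernel: np.ndarray
    pixel_size_um: float
    fwhm_um: float
    provenance: str = "theoretical"
    n_beads_averaged: int = 0

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 2:
            raise ConfigurationError("PSF kernel must be 2-D")
        if np.any(k < 0):
            raise ConfigurationError("PSF kernel must be nonnegative")
        s = k.sum()
        if s <= 0:
            raise ConfigurationError("PSF kernel must have positive total mass")
        if not math.isclose(s, 1.0, rel_tol=0, abs_tol=1e-9):
            k = k / s
        cy, cx = k.shape[0] // 2, k.shape[1] // 2
        my, mx = np.unravel_index(np.argmax(k), k.shape)
        off = math.hypot(my - cy, mx - cx)
        if off > 1.5:
            raise ConfigurationError(
                f"PSF kernel maximum is {off:.1f} px off-centre"
            )
        if off > 0:
            warnings.warn(
                "PSF kernel maximum is adjacent to, not at, the centre "
                "(noise in an empirical estimate)", stacklevel=2,
            )
        self.kernel = k

    @property
    def fwhm_px(self) -> float:
        return self.fwhm_um / self.pixel_size_um


# ---------------------------------------------------------------------------
# Resolution arithmetic
# ---------------------------------------------------------------------------


def abbe_limit(optics: OpticalConfig) -> float:
    """Diffraction-limited resolution λ/(2·NA), in nm."""
    na = optics.na
    if na <= 0:
        raise ConfigurationError("numerical aperture must be > 0")
    return optics.wavelength_nm / (2.0 * na)


def effective_resolution(optics: OpticalConfig, mode: str) -> float:
    """Photon-limited effective resolution, in nm.

    ``superresolution`` scales the Abbe limit by N^(-1/2); ``deconvolution``
    by N^(-1/4).
    """
    if optics.photon_count < 1:
        raise ConfigurationError("photon_count must be ≥ 1")
    base = abbe_limit(optics)
    if mode == "superresolution":
        return base * optics.photon_count ** -0.5
    if mode == "deconvolution":
        return base * optics.photon_count ** -0.25
    raise ConfigurationError(f"unknown mode {mode!r}")


def photons_required(
    optics: OpticalConfig, target_resolution_nm: float, mode: str
) -> float:
    """Smallest photon count N whose effective resolution reaches the target."""
    base = abbe_limit(optics)
    if target_resolution_nm >= base:
        warnings.warn(
            "target resolution is not below the Abbe limit; one photon suffices",
            stacklevel=2,
        )
        return 1.0
    ratio = base / target_resolution_nm
    if mode == "superresolution":
        n = ratio**2
    elif mode == "deconvolution":
        n = ratio**4
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    # round up, but absorb floating-point dust so an exact 2x gain gives N=4
    return float(math.ceil(n - 1e-9))


# ---------------------------------------------------------------------------
# PSF construction and measurement
# ---------------------------------------------------------------------------


def _gaussian_kernel(sigma_px: float, support: int) -> np.ndarray:
    ax = np.arange(support) - support // 2
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(yy**2 + xx**2) / (2.0 * sigma_px**2))
    return k / k.sum()


def theoretical_psf(
    optics: OpticalConfig, pixel_size_um: float, support: int = 0
) -> PSFModel:
    """Isotropic Gaussian PSF with FWHM equal to the Abbe limit.

    A Gaussian is an adequate stand-in for the Airy disk core for the
    pipeline's purposes; an empirical PSF should be preferred on real systems
    where aberrations dominate.
    """
    if pixel_size_um <= 0:
        raise ConfigurationError("pixel_size_um must be > 0")
    fwhm_um = abbe_limit(optics) / 1000.0
    if pixel_size_um >= fwhm_um / 2:
        raise ConfigurationError(
            f"pixel size {pixel_size_um} µm undersamples a PSF of FWHM "
            f"{fwhm_um:.4f} µm (Nyquist requires pixel < FWHM/2)"
        )
    sigma_px = fwhm_um / pixel_size_um / GAUSSIAN_FWHM_PER_SIGMA
    if support == 0:
        support = int(2 * math.ceil(4 * sigma_px) + 1)
    if support % 2 == 0:
        raise ConfigurationError("PSF support must be odd-sized")
    if support < 4 * sigma_px:
        raise ConfigurationError("PSF support too small for the requested FWHM")
    kernel = _gaussian_kernel(sigma_px, support)
    return PSFModel(
        kernel=kernel,
        pixel_size_um=pixel_size_um,
        fwhm_um=fwhm_um,
        provenance="theoretical",
    )


def identity_psf(pixel_size_um: float, support: int = 1) -> PSFModel:
    """Delta kernel: no blur.  Useful as a null model in tests and simulation."""
    if support % 2 == 0:
        raise ConfigurationError("PSF support must be odd-sized")
    k = np.zeros((support, support))
    k[support // 2, support // 2] = 1.0
    return PSFModel(kernel=k, pixel_size_um=pixel_size_um, fwhm_um=0.0,
                    provenance="theoretical")


def gaussian_psf(
    fwhm_um: float, pixel_size_um: float, support: int = 0
) -> PSFModel:
    """Gaussian PSF of a given physical FWHM (convenience constructor)."""
    if fwhm_um <= 0 or pixel_size_um <= 0:
        raise ConfigurationError("fwhm_um and pixel_size_um must be > 0")
    sigma_px = fwhm_um / pixel_size_um / GAUSSIAN_FWHM_PER_SIGMA
    if support == 0:
        support = int(2 * math.ceil(4 * sigma_px) + 1)
    if support % 2 == 0:
        raise ConfigurationError("PSF support must be odd-sized")
    return PSFModel(
        kernel=_gaussian_kernel(sigma_px, support),
        pixel_size_um=pixel_size_um,
        fwhm_um=fwhm_um,
        provenance="theoretical",
    )


def augment_psf_with_gaussian(psf: PSFModel, sigma_px: float) -> PSFModel:
    """PSF of the optics followed by a Gaussian denoising filter.

    Pre-filtering an image with a Gaussian of σ ``sigma_px`` is equivalent to
    imaging through a wider PSF; deconvolving the filtered image with this
    combined kernel removes both blurs in one well-conditioned step.
    """
    from scipy import signal as _signal

    if sigma_px <= 0:
        return psf
    g = _gaussian_kernel(sigma_px, int(2 * math.ceil(4 * sigma_px) + 1))
    k = _signal.convolve2d(psf.kernel, g)
    k /= k.sum()
    return PSFModel(
        kernel=k,
        pixel_size_um=psf.pixel_size_um,
        fwhm_um=kernel_fwhm_px(k) * psf.pixel_size_um,
        provenance=psf.provenance,
        n_beads_averaged=psf.n_beads_averaged,
    )


def kernel_fwhm_px(kernel: np.ndarray) -> float:
    """FWHM of a centred kernel's radial profile, in pixels.

    The radial profile is sampled by angular averaging of the bilinearly
    interpolated kernel; the half-maximum crossing is located by linear
    interpolation between samples.
    """
    k = np.asarray(kernel, dtype=float)
    cy, cx = k.shape[0] // 2, k.shape[1] // 2
    r_max = min(cy, cx)
    radii = np.linspace(0, r_max, int(r_max * 40) + 1)
    angles = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    rr, aa = np.meshgrid(radii, angles, indexing="ij")
    ys = cy + rr * np.sin(aa)
    xs = cx + rr * np.cos(aa)
    prof = ndimage.map_coordinates(
        k, np.stack([ys.ravel(), xs.ravel()]), order=3, mode="nearest"
    ).reshape(rr.shape).mean(axis=1)
    half = prof[0] / 2.0
    below = np.nonzero(prof < half)[0]
    if below.size == 0:
        raise ValueError("kernel does not fall below half maximum inside support")
    i = below[0]
    # linear interpolation of the crossing radius
    r0, r1 = radii[i - 1], radii[i]
    p0, p1 = prof[i - 1], prof[i]
    r_half = r0 + (p0 - half) / (p0 - p1) * (r1 - r0)
    return 2.0 * r_half


def radial_symmetrize(kernel: np.ndarray) -> np.ndarray:
    """Average a centred kernel over its circular axes.

    Preserves unit sum and the centre of mass (which moves to the exact
    centre by construction).
    """
    k = np.asarray(kernel, dtype=float)
    cy, cx = k.shape[0] // 2, k.shape[1] // 2
    yy, xx = np.indices(k.shape)
    r = np.hypot(yy - cy, xx - cx)
    r_max = r.max()
    radii = np.linspace(0, r_max, int(r_max * 10) + 2)
    angles = np.linspace(0, 2 * np.pi, 90, endpoint=False)
    rr, aa = np.meshgrid(radii, angles, indexing="ij")
    samples = ndimage.map_coordinates(
        k,
        np.stack([cy + rr.ravel() * np.sin(aa.ravel()),
                  cx + rr.ravel() * np.cos(aa.ravel())]),
        order=1,
        mode="constant",
    ).reshape(rr.shape)
    prof = samples.mean(axis=1)
    out = np.interp(r.ravel(), radii, prof).reshape(k.shape)
    out = np.clip(out, 0, None)
    return out / out.sum() * k.sum()


def _weighted_centroid(window: np.ndarray) -> tuple[float, float]:
    w = np.clip(window, 0, None)
    tot = w.sum()
    if tot <= 0:
        return (window.shape[0] / 2.0 - 0.5, window.shape[1] / 2.0 - 0.5)
    yy, xx = np.indices(window.shape)
    return float((w * yy).sum() / tot), float((w * xx).sum() / tot)


def estimate_psf_from_beads(
    bead_stack: MovieStack,
    expected_fwhm_px: float = 4.0,
    threshold_rel: float = 0.2,
    symmetrize: bool = False,
) -> PSFModel:
    """Estimate the PSF by averaging bead images across beads and trials.

    Each frame of ``bead_stack`` is one acquisition trial.  Spots are detected
    as local maxima above ``threshold_rel`` × frame max, a window of about 6×
    the expected FWHM is cut around each, the median of the window's border
    ring is subtracted as background, the spot is centred to sub-pixel
    accuracy (intensity-weighted centroid, iterated twice, applied by Fourier
    shift), and all centred spots are averaged and normalized to unit sum.

    Beads closer than the window size to each other overlap and are excluded
    with a warning.  Bead diameter is not deconvolved out of the estimate; use
    beads smaller than half the resolution.
    """
    from skimage.feature import peak_local_max

    half = int(math.ceil(3 * expected_fwhm_px))
    win = 2 * half + 1
    accum = np.zeros((win, win))
    n_spots = 0
    n_overlap = 0
    for frame in np.asarray(bead_stack.data, dtype=float):
        if frame.max() <= 0:
            continue
        peaks = peak_local_max(
            frame,
            min_distance=max(2, int(expected_fwhm_px)),
            threshold_abs=threshold_rel * frame.max(),
        )
        # exclude overlapping beads: nearest peak closer than the window
        for py, px in peaks:
            d_near = np.inf
            for qy, qx in peaks:
                if (qy, qx) != (py, px):
                    d_near = min(d_near, math.hypot(py - qy, px - qx))
            if d_near < win:
                n_overlap += 1
                continue
            if not (half <= py < frame.shape[0] - half
                    and half <= px < frame.shape[1] - half):
                continue
            window = frame[py - half:py + half + 1, px - half:px + half + 1].copy()
            border = np.concatenate(
                [window[0], window[-1], window[1:-1, 0], window[1:-1, -1]]
            )
            window -= np.median(border)
            window = np.clip(window, 0, None)
            # two rounds of centroid refinement, then recentre by Fourier shift
            dy = dx = 0.0
            for _ in range(2):
                probe = _fourier_shift(window, (-dy, -dx)) if (dy or dx) else window
                cy, cx = _weighted_centroid(probe)
                dy += cy - half
                dx += cx - half
            centred = _fourier_shift(window, (-dy, -dx))
            accum += np.clip(centred, 0, None)
            n_spots += 1
    if n_overlap:
        warnings.warn(
            f"excluded {n_overlap} overlapping bead image(s)", stacklevel=2
        )
    if n_spots == 0:
        raise ValueError("no beads detected in the stack")
    kernel = accum / n_spots
    if symmetrize:
        kernel = radial_symmetrize(kernel)
    kernel = np.clip(kernel, 0, None)
    kernel /= kernel.sum()
    fwhm_px = kernel_fwhm_px(kernel)
    return PSFModel(
        kernel=kernel,
        pixel_size_um=bead_stack.pixel_size_um,
        fwhm_um=fwhm_px * bead_stack.pixel_size_um,
        provenance="empirical",
        n_beads_averaged=n_spots,
    )


def _fourier_shift(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Sub-pixel shift by Fourier phase ramp (band-limited, non-broadening)."""
    if shift == (0.0, 0.0):
        return image.copy()
    f = np.fft.fftn(image)
    f = ndimage.fourier_shift(f, shift)
    return np.real(np.fft.ifftn(f))
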