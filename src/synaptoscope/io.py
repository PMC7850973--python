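"""File formats: multi-page TIFF movies with JSON metadata sidecars.

A movie is stored as a grayscale multi-page TIFF (time as pages) plus a
sidecar ``<path>.json`` holding pixel size, frame rate, stimulus times and
the provenance log.  PSFs are stored the same way (single page).  Round-trip
write→read is lossless for unsigned 8/16-bit and 32/64-bit float data.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .core import ConfigurationError, MovieStack
from .optics import PSFModel

__all__ = [
    "read_movie",
    "write_movie",
    "read_psf",
    "write_psf",
    "read_stimulus_times",
    "write_json",
]

_SUPPORTED_DTYPES = ("uint8", "uint16", "float32", "float64")


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a movie as multi-page TIFF + JSON sidecar; returns the TIFF path."""
    path = Path(path)
    data = np.asarray(movie.data)
    if data.dtype.name not in _SUPPORTED_DTYPES:
        raise ConfigurationError(
            f"unsupported dtype {data.dtype}; use one of {_SUPPORTED_DTYPES}"
        )
    bigtiff = data.nbytes > 2**31 - 2**25
    tifffile.imwrite(path, data, bigtiff=bigtiff, photometric="minisblack")
    meta = {
        "pixel_size_um": movie.pixel_size_um,
        "frame_rate_hz": movie.frame_rate_hz,
        "stimulus_times_s": movie.stimulus_times_s,
        "provenance": movie.provenance,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=_jsonify))
    return path


def read_movie(
    path: str | Path,
    pixel_size_um: float | None = None,
    frame_rate_hz: float | None = None,
    stimulus_times_s: list[float] | None = None,
) -> MovieStack:
    """Read a grayscale multi-page TIFF movie.

    Metadata comes from the JSON sidecar if present; explicit arguments
    override it.  Missing pixel size or frame rate is an error — physical
    calibration is required downstream.  RGB / multi-sample TIFFs are
    rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        axes = tif.series[0].axes
        if "S" in axes:
            raise ConfigurationError(
                "RGB/multi-sample TIFF not supported: convert to grayscale"
            )
        data = tif.series[0].asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ConfigurationError(
            f"expected a (time, y, x) stack; got axes {axes!r} shape {data.shape}"
        )
    meta: dict = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    fr = frame_rate_hz if frame_rate_hz is not None else meta.get("frame_rate_hz")
    stim = (stimulus_times_s if stimulus_times_s is not None
            else meta.get("stimulus_times_s"))
    if px is None or fr is None:
        raise ConfigurationError(
            "pixel_size_um and frame_rate_hz required: supply them as "
            "arguments/flags or in the JSON sidecar"
        )
    return MovieStack(
        data=data,
        pixel_size_um=float(px),
        frame_rate_hz=float(fr),
        stimulus_times_s=list(stim) if stim else None,
        provenance=list(meta.get("provenance", [])) + [
            {"step": "read", "path": str(path)}
        ],
    )


def write_psf(psf: PSFModel, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, psf.kernel.astype(np.float64),
                     photometric="minisblack")
    meta = {
        "pixel_size_um": psf.pixel_size_um,
        "fwhm_um": psf.fwhm_um,
        "provenance": psf.provenance,
        "n_beads_averaged": psf.n_beads_averaged,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_psf(path: str | Path) -> PSFModel:
    path = Path(path)
    kernel = tifffile.imread(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ConfigurationError(f"PSF sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    return PSFModel(
        kernel=kernel,
        pixel_size_um=float(meta["pixel_size_um"]),
        fwhm_um=float(meta["fwhm_um"]),
        provenance=meta.get("provenance", "empirical"),
        n_beads_averaged=int(meta.get("n_beads_averaged", 0)),
    )


def read_stimulus_times(path: str | Path) -> list[float]:
    """Stimulus times in seconds from a plain text/CSV file (one per line or
    comma-separated)."""
    text = Path(path).read_text().replace(",", "\n")
    return [float(tok) for tok in text.split() if tok.strip()]


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=_jsonify))
    return path
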