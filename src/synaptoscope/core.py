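"""Shared containers and error types for the sensor-imaging pipeline.

Conventions used throughout the package:

* image axes are ``(time, row, col)``; pixel indices are 0-based
* physical positions are in micrometres from the centre of pixel ``(0, 0)``
* time is in seconds from the first frame; a stimulus at time ``t`` lands in
  frame ``floor(t * frame_rate)``
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfigurationError",
    "PipelineError",
    "MovieStack",
    "DffStack",
]


class ConfigurationError(ValueError):
    """Invalid configuration or parameter value."""


class PipelineError(RuntimeError):
    """A pipeline stage failed in a way that should halt processing."""


@dataclass
class MovieStack:
    """A fluorescence movie: ``(time, y, x)`` intensities plus acquisition metadata.

    Intensities are photon-count-scaled and nonnegative before ΔF/F
    computation.  ``provenance`` is an append-only log of the operations that
    produced this stack.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_rate_hz: float
    stimulus_times_s: list[float] | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError(
                f"movie data must be 3-D (time, y, x); got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be > 0")
        if self.frame_rate_hz <= 0:
            raise ConfigurationError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def stimulus_frames(self) -> np.ndarray:
        """Frame index for each stimulus: ``floor(t * frame_rate)``."""
        if not self.stimulus_times_s:
            return np.array([], dtype=int)
        return np.floor(
            np.asarray(self.stimulus_times_s) * self.frame_rate_hz
        ).astype(int)

    def with_data(self, data: np.ndarray, step: str, **params) -> "MovieStack":
        """Copy of this stack with new pixel data and a provenance entry appended."""
        new = dataclasses.replace(self, data=data)
        new.provenance = list(self.provenance) + [{"step": step, **params}]
        return new

    def log(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})


@dataclass
class DffStack:
    """Fractional fluorescence change ΔF/F = (F − F0)/F0 over time.

    ``baseline_f0`` is the per-pixel baseline image; pixels where F0 was not
    positive are masked (``valid_mask`` False, dff forced to 0 there).
    """

    dff: np.ndarray
    baseline_f0: np.ndarray
    baseline_window: tuple[int, int]
    pixel_size_um: float
    frame_rate_hz: float
    stimulus_times_s: list[float] | None = None
    valid_mask: np.ndarray | None = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dff = np.asarray(self.dff, dtype=float)
        if self.dff.ndim != 3:
            raise ConfigurationError("dff must be 3-D (time, y, x)")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.dff.shape[1:], dtype=bool)
        if not np.all(np.isfinite(self.dff)):
            raise ConfigurationError("dff contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.dff.shape[0]

    @property
    def frame_times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def stimulus_frames(self) -> np.ndarray:
        if not self.stimulus_times_s:
            return np.array([], dtype=int)
        return np.floor(
            np.asarray(self.stimulus_times_s) * self.frame_rate_hz
        ).astype(int)
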