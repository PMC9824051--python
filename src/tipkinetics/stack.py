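"""Calibrated time-lapse container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError


@dataclass
class TimeLapseStack:
    """A single-channel fluorescence time lapse with physical calibration.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Intensities in arbitrary units, finite and non-negative.
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    dt : float
        Frame interval in seconds.
    """

    frames: np.ndarray
    pixel_size: float
    dt: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ParameterError("stack must be 3-D (time, row, col) with >= 2 frames")
        if not (self.pixel_size > 0):
            raise ParameterError("pixel_size must be > 0")
        if not (self.dt > 0):
            raise ParameterError("dt must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise ParameterError("stack intensities must be finite")
        if np.any(self.frames < 0):
            raise ParameterError("stack intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) * self.dt
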