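"""Calibrated image containers.

Every measurement in this package is expressed in physical units:
micrometres for length, seconds for time, arbitrary fluorescence units
(AU) for intensity.  The containers here pair raw pixel data with that
calibration so downstream code never has to guess a pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalibratedImage", "ImageStack", "DegenerateImageError"]


class DegenerateImageError(ValueError):
    """Raised when an image cannot support the requested measurement
    (constant, saturated or otherwise uninformative)."""


@dataclass(frozen=True)
class CalibratedImage:
    """A single 2-D fluorescence image with physical pixel size.

    Parameters
    ----------
    pixels:
        2-D array of non-negative intensities in AU, indexed [row, col].
    pixel_size:
        Edge length of one pixel in micrometres (µm/pixel); must be > 0.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels must be finite")
        if np.any(px < 0):
            raise ValueError("pixels must be non-negative (AU)")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) of the field of view in µm."""
        h, w = self.pixels.shape
        return (h * self.pixel_size, w * self.pixel_size)


@dataclass(frozen=True)
class ImageStack:
    """An ordered time-lapse of equally calibrated frames.

    ``frames`` is a 3-D array indexed [t, row, col]; ``frame_interval``
    is the time between consecutive frames in seconds.
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=float)
        if fr.ndim != 3:
            raise ValueError(f"frames must be 3-D (t, y, x), got shape {fr.shape}")
        if not np.all(np.isfinite(fr)):
            raise ValueError("frames must be finite")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not self.frame_interval > 0:
            raise ValueError(f"frame_interval must be > 0, got {self.frame_interval}")
        object.__setattr__(self, "frames", fr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Total covered time span in seconds (n_frames × interval)."""
        return self.n_frames * self.frame_interval

    def frame(self, t: int) -> CalibratedImage:
        return CalibratedImage(self.frames[t], self.pixel_size)

    def __iter__(self):
        for t in range(self.n_frames):
            yield self.frame(t)
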