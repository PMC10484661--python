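"""Core in-memory container for a single-channel fluorescence field."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FieldImage"]


@dataclass
class FieldImage:
    """A 2D single-channel intensity image with physical pixel size.

    Parameters
    ----------
    data:
        2D array of intensities in native camera units (ADU). Stored as
        float64 so that downstream statistics are not limited by the
        acquisition bit depth.
    pixel_size_um:
        Physical size of one pixel edge in micrometres. Required for every
        measurement that reports areas, diameters or lengths.
    channel:
        Free-form channel label (e.g. ``"488"`` for a Broccoli/DFHBI-1T
        channel, ``"561"`` for Pepper/HBC620).
    """

    data: np.ndarray
    pixel_size_um: float
    channel: str = "488"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"FieldImage requires a 2D array, got ndim={self.data.ndim}")
        if self.data.size == 0:
            raise ValueError("FieldImage requires a non-empty array")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    @property
    def area_um2(self) -> float:
        """Physical area of the whole field of view in μm²."""
        return self.data.size * self.pixel_area_um2

    def copy(self) -> "FieldImage":
        return FieldImage(self.data.copy(), self.pixel_size_um, self.channel, dict(self.meta))
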