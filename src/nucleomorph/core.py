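"""Shared containers for nucleus images and masks.

All images are 2D float arrays in row-major order (origin top-left, pixel
centers at integer coordinates); intensities are kept in floating point,
normalized to [0, 1], regardless of the source bit depth.  Masks and the
images they describe share the same pixel grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = ["NucleusImage", "NucleusMask", "FOUR_CONNECTED"]

#: 4-connectivity structuring element used for all connected-component logic.
FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class NucleusImage:
    """One grayscale intensity array with pixel-size calibration.

    Parameters
    ----------
    pixels : 2D float array
        Nonnegative intensities, typically normalized to [0, 1].
    pixel_size_um : float
        Physical edge length of one pixel in micrometers.
    provenance : list of str
        Human-readable log of the processing steps applied so far.
    """

    pixels: np.ndarray
    pixel_size_um: float
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("NucleusImage.pixels must be 2D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("NucleusImage.pixels must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("NucleusImage.pixels must be nonnegative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, step: str) -> "NucleusImage":
        """Return a copy holding ``pixels`` with ``step`` appended to provenance."""
        return NucleusImage(
            pixels=pixels,
            pixel_size_um=self.pixel_size_um,
            provenance=[*self.provenance, step],
        )


@dataclass
class NucleusMask:
    """Binary mask of a single segmented nucleus.

    ``pixels`` is the mask crop; ``bbox`` = (min_row, min_col, max_row, max_col)
    locates the crop inside its parent image (half-open, numpy slicing
    convention).  The foreground must be one non-empty 4-connected component.
    """

    pixels: np.ndarray
    bbox: tuple = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("NucleusMask.pixels must be 2D")
        if not self.pixels.any():
            raise ValueError("NucleusMask is empty")
        _, n = ndi.label(self.pixels, structure=FOUR_CONNECTED)
        if n != 1:
            raise ValueError(
                f"NucleusMask must be a single 4-connected component (found {n})"
            )
        if self.bbox is None:
            self.bbox = (0, 0, self.pixels.shape[0], self.pixels.shape[1])

    @property
    def area_px(self) -> int:
        """Foreground pixel count."""
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple:
        return self.pixels.shape
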