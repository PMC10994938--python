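"""The 2-D grayscale image container used throughout the package.

MR magnitude images are nonnegative real grids with a physical pixel
spacing.  Every operator in this package consumes and produces
:class:`GrayImage` so that field-of-view bookkeeping (``shape * spacing``)
is carried through degradation, up-sampling and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GrayImage"]


@dataclass(frozen=True)
class GrayImage:
    """A 2-D real-valued image with physical pixel spacing.

    Parameters
    ----------
    pixels:
        2-D array of intensities (arbitrary units, nonnegative for
        magnitude images).
    spacing:
        ``(row, col)`` pixel size in millimetres.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={px.ndim}")
        if px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"image too small: shape={px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        sp = (float(self.spacing[0]), float(self.spacing[1]))
        if sp[0] <= 0 or sp[1] <= 0:
            raise ValueError(f"pixel spacing must be positive, got {sp}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def fov(self) -> tuple[float, float]:
        """Field of view in mm: ``shape * spacing`` per axis."""
        return (self.shape[0] * self.spacing[0], self.shape[1] * self.spacing[1])

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Same geometry, new pixel values (shape must match)."""
        if pixels.shape != self.pixels.shape:
            raise ValueError("with_pixels requires identical shape")
        return GrayImage(pixels, self.spacing)
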