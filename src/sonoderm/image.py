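"""2-D image container shared by the phantom, denoising and measurement modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Image2D"]


@dataclass(frozen=True)
class Image2D:
    """A 2-D grid of finite real intensities.

    Parameters
    ----------
    pixels
        2-D array of intensities. Stored as float64; must be finite.
    pixel_spacing
        Optional isotropic physical spacing in mm/pixel. Required by
        operations that convert between pixels and millimetres (shell
        rings, thickness measurement).
    """

    pixels: np.ndarray
    pixel_spacing: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"pixels must be non-empty, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("pixels contain NaN or Inf")
        object.__setattr__(self, "pixels", arr)
        if self.pixel_spacing is not None:
            sp = float(self.pixel_spacing)
            if not np.isfinite(sp) or sp <= 0:
                raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
            object.__setattr__(self, "pixel_spacing", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Return a new image with the same spacing but different pixels."""
        return Image2D(pixels=pixels, pixel_spacing=self.pixel_spacing)

    def require_spacing(self) -> float:
        if self.pixel_spacing is None:
            raise ValueError("operation requires pixel_spacing (mm/pixel) to be set")
        return self.pixel_spacing
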