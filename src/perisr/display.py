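"""Physical rendering context of the simulated CRT display.

All geometry is expressed in arcmin of visual angle relative to the
fixation point, with x increasing toward the temporal field (rightward)
and y increasing upward.  Images are row-major with row 0 at the top, so
pixel (i, j) has its center at::

    x = x_left + (j + 0.5) * arcmin_per_pixel
    y = y_top  - (i + 0.5) * arcmin_per_pixel

The default canvas is a scene window centered on the 10 deg meridian
point, large enough to contain the 7 deg x 7 deg occluder mask at every
configured path position.  :meth:`DisplayModel.full_field` yields a wider
canvas that also contains the central fixation cross, for export and
illustration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

#: Eccentricity of the target region, arcmin (10 deg on the horizontal meridian).
MERIDIAN_POINT = (600.0, 0.0)


@dataclass(frozen=True)
class DisplayModel:
    """Frame rate, pixel pitch, luminances and canvas of the display.

    Parameters
    ----------
    frame_rate:
        Refresh rate in Hz.
    arcmin_per_pixel:
        Visual angle subtended by one screen pixel, arcmin.
    background_luminance, target_luminance:
        Gray background and white target luminance, cd/m^2.
    canvas_center, canvas_extent:
        Center and (width, height) of the rendered canvas, arcmin
        relative to fixation.
    """

    frame_rate: float = 75.0
    arcmin_per_pixel: float = 1.05
    background_luminance: float = 45.0
    target_luminance: float = 85.0
    canvas_center: tuple[float, float] = MERIDIAN_POINT
    canvas_extent: tuple[float, float] = (480.0, 480.0)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ParameterError("frame_rate must be positive")
        if self.arcmin_per_pixel <= 0:
            raise ParameterError("arcmin_per_pixel must be positive")
        if self.target_luminance <= self.background_luminance:
            raise ParameterError("target_luminance must exceed background_luminance")
        if min(self.canvas_extent) <= 0:
            raise ParameterError("canvas_extent must be positive")

    @classmethod
    def full_field(cls, **kwargs) -> "DisplayModel":
        """Canvas containing both the fixation cross and the mask region."""
        kwargs.setdefault("canvas_center", (400.0, 0.0))
        kwargs.setdefault("canvas_extent", (880.0, 480.0))
        return cls(**kwargs)

    # -- derived raster geometry -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the rasterized canvas."""
        h = int(round(self.canvas_extent[1] / self.arcmin_per_pixel))
        w = int(round(self.canvas_extent[0] / self.arcmin_per_pixel))
        return h, w

    @property
    def x_left(self) -> float:
        return self.canvas_center[0] - self.canvas_extent[0] / 2.0

    @property
    def y_top(self) -> float:
        return self.canvas_center[1] + self.canvas_extent[1] / 2.0

    def col_centers(self) -> np.ndarray:
        """x coordinate (arcmin) of every pixel-column center."""
        w = self.shape[1]
        return self.x_left + (np.arange(w) + 0.5) * self.arcmin_per_pixel

    def row_centers(self) -> np.ndarray:
        """y coordinate (arcmin) of every pixel-row center."""
        h = self.shape[0]
        return self.y_top - (np.arange(h) + 0.5) * self.arcmin_per_pixel

    def to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Continuous (row, col) pixel coordinates of an arcmin position."""
        col = (x - self.x_left) / self.arcmin_per_pixel - 0.5
        row = (self.y_top - y) / self.arcmin_per_pixel - 0.5
        return row, col

    def contains(self, x: float, y: float, margin: float = 0.0) -> bool:
        """Whether a point (plus margin, arcmin) lies inside the canvas."""
        return (
            self.x_left + margin <= x <= self.x_left + self.canvas_extent[0] - margin
            and self.y_top - self.canvas_extent[1] + margin <= y <= self.y_top - margin
        )

    def blank_canvas(self) -> np.ndarray:
        """New canvas filled with the background luminance (float32)."""
        return np.full(self.shape, self.background_luminance, dtype=np.float32)
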