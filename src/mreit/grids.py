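"""Pixel-grid geometry shared by every module.

Conventions (used everywhere in the package):

* arrays are indexed ``[row, col]`` = ``[iy, ix]`` with shape ``(ny, nx)``;
* ``x`` runs along columns, ``y`` along rows, both 0-based;
* physical position of pixel center ``(ix, iy)`` is
  ``origin + (ix * dx, iy * dy)`` with *y increasing upward*;
* all physical lengths are in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class SliceGrid:
    """Regular pixel grid of one imaging slice.

    Parameters
    ----------
    nx, ny : int
        Pixel counts along x (columns) and y (rows); at least 8 each.
    dx, dy : float
        In-plane pixel spacing in meters.
    dz : float
        Slice thickness in meters.
    origin : (float, float)
        Physical coordinate of the center of pixel (0, 0).
    """

    nx: int
    ny: int
    dx: float
    dy: float
    dz: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.nx < 8 or self.ny < 8:
            raise ValidationError(f"grid must be at least 8x8, got {self.nx}x{self.ny}")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValidationError("pixel spacings dx, dy, dz must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(ny, nx)``."""
        return (self.ny, self.nx)

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + self.dx * np.arange(self.nx)

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + self.dy * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (X, Y) coordinates of all pixel centers, shape (ny, nx)."""
        return np.meshgrid(self.x_coords(), self.y_coords())

    def center(self) -> tuple[float, float]:
        return (
            self.origin[0] + 0.5 * self.dx * (self.nx - 1),
            self.origin[1] + 0.5 * self.dy * (self.ny - 1),
        )

    def physical_to_pixel(self, points: np.ndarray) -> np.ndarray:
        """Map physical (x, y) points, shape (..., 2), to fractional pixel indices."""
        pts = np.asarray(points, dtype=float)
        out = np.empty_like(pts)
        out[..., 0] = (pts[..., 0] - self.origin[0]) / self.dx
        out[..., 1] = (pts[..., 1] - self.origin[1]) / self.dy
        return out


def bilinear_sample(field: np.ndarray, grid: SliceGrid, points: np.ndarray,
                    fill: float = 0.0) -> np.ndarray:
    """Bilinearly sample a (ny, nx) pixel field at physical points (..., 2).

    NaNs in `field` and out-of-frame points yield `fill`.
    """
    pix = grid.physical_to_pixel(points)
    fx, fy = pix[..., 0], pix[..., 1]
    ix0 = np.clip(np.floor(fx).astype(int), 0, grid.nx - 2)
    iy0 = np.clip(np.floor(fy).astype(int), 0, grid.ny - 2)
    tx = np.clip(fx - ix0, 0.0, 1.0)
    ty = np.clip(fy - iy0, 0.0, 1.0)
    f = np.asarray(field, dtype=float)
    v = ((1 - tx) * (1 - ty) * f[iy0, ix0]
         + tx * (1 - ty) * f[iy0, ix0 + 1]
         + (1 - tx) * ty * f[iy0 + 1, ix0]
         + tx * ty * f[iy0 + 1, ix0 + 1])
    outside = (fx < -0.5) | (fx > grid.nx - 0.5) | (fy < -0.5) | (fy > grid.ny - 0.5)
    v = np.where(outside | ~np.isfinite(v), fill, v)
    return v
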