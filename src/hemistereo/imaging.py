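"""Image containers, colour transform and circular-geometry helpers.

A hemispherical (fisheye) photograph is a circular image: only pixels
inside the disc of radius ``radius_px`` around the optical-axis centre
carry scene content.  Every later stage works on that disc, and polar
coordinates about the centre are the natural frame (the polar angle is
what the disparity is measured in).

Coordinate conventions used throughout the package:

* array coordinates are 0-based ``(row, col)``, row increasing downward;
* centred "mathematical" coordinates are ``x = col - centre_col`` and
  ``y = centre_row - row`` (row axis flipped), so the polar angle theta
  is measured counter-clockwise from the +x axis in ``[0, 360)`` degrees;
* the centre pixel (r = 0) has theta = 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np

__all__ = [
    "HemisphericalImage",
    "PolarCoord",
    "rgb_to_intensity",
    "cartesian_to_polar",
    "polar_to_cartesian",
    "polar_angle_map",
    "radius_map",
    "circular_angle_difference",
    "centred_xy",
    "rowcol_from_xy",
    "read_image",
    "write_image",
    "write_mask",
]


@dataclass
class HemisphericalImage:
    """Circular RGB image with its radius, centre and valid-pixel mask."""

    pixels: np.ndarray          # (H, W, 3) uint8
    radius_px: float
    centre: tuple[float, float]  # (row, col) of the optical axis
    valid_mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit (uint8)")
        if not self.radius_px > 0:
            raise ValueError("radius_px must be positive")
        h, w = self.pixels.shape[:2]
        cr, cc = self.centre
        if not (0 <= cr < h and 0 <= cc < w):
            raise ValueError("centre must lie inside the image bounds")
        if self.valid_mask is None:
            self.valid_mask = self._disc_mask()
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (h, w):
                raise ValueError("valid_mask shape mismatch")

    def _disc_mask(self) -> np.ndarray:
        h, w = self.pixels.shape[:2]
        rows, cols = np.mgrid[0:h, 0:w]
        d = np.hypot(rows - self.centre[0], cols - self.centre[1])
        return d <= self.radius_px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @classmethod
    def from_array(
        cls,
        pixels: np.ndarray,
        radius_px: float | None = None,
        centre: tuple[float, float] | None = None,
    ) -> "HemisphericalImage":
        """Wrap an RGB array; centre/radius default to the inscribed disc."""
        pixels = np.asarray(pixels, dtype=np.uint8)
        h, w = pixels.shape[:2]
        if centre is None:
            centre = ((h - 1) / 2.0, (w - 1) / 2.0)
        if radius_px is None:
            radius_px = min((h - 1) / 2.0, (w - 1) / 2.0)
        return cls(pixels=pixels, radius_px=float(radius_px), centre=centre)


@dataclass(frozen=True)
class PolarCoord:
    """Polar position about the image centre: radius (px), angle (deg)."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be non-negative")
        if not (0.0 <= self.theta < 360.0):
            raise ValueError("theta must lie in [0, 360)")


def rgb_to_intensity(image) -> np.ndarray:
    """HSI intensity I = (R + G + B) / 3 on the 0-255 scale."""
    pixels = image.pixels if isinstance(image, HemisphericalImage) else np.asarray(image)
    return pixels.astype(np.float64).sum(axis=-1) / 3.0


def centred_xy(pixel: tuple[float, float], centre: tuple[float, float]) -> tuple[float, float]:
    """(row, col) -> centred (x, y) with the row axis flipped."""
    row, col = pixel
    return col - centre[1], centre[0] - row


def rowcol_from_xy(x, y, centre: tuple[float, float]):
    """Centred (x, y) -> (row, col); inverse of :func:`centred_xy`."""
    return centre[0] - np.asarray(y), centre[1] + np.asarray(x)


def cartesian_to_polar(pixel: tuple[float, float], image: HemisphericalImage) -> PolarCoord:
    """Polar coordinates of a pixel about the image centre.

    Raises ``ValueError`` for pixels outside the valid disc.  The centre
    pixel maps to ``(r=0, theta=0)`` by convention.
    """
    x, y = centred_xy(pixel, image.centre)
    r = float(np.hypot(x, y))
    if r > image.radius_px:
        raise ValueError(f"pixel {pixel} lies outside the valid disc")
    if r == 0.0:
        return PolarCoord(0.0, 0.0)
    theta = float(np.degrees(np.arctan2(y, x)) % 360.0)
    return PolarCoord(r, theta)


def polar_to_cartesian(coord: PolarCoord, image: HemisphericalImage) -> tuple[float, float]:
    th = np.radians(coord.theta)
    x = coord.r * np.cos(th)
    y = coord.r * np.sin(th)
    row, col = rowcol_from_xy(x, y, image.centre)
    return float(row), float(col)


def polar_angle_map(image: HemisphericalImage) -> np.ndarray:
    """Per-pixel polar angle (degrees in [0, 360)); centre pixel gets 0."""
    h, w = image.shape
    rows, cols = np.mgrid[0:h, 0:w]
    x = cols - image.centre[1]
    y = image.centre[0] - rows
    theta = np.degrees(np.arctan2(y, x)) % 360.0
    theta[(x == 0) & (y == 0)] = 0.0
    return theta


def radius_map(image: HemisphericalImage) -> np.ndarray:
    h, w = image.shape
    rows, cols = np.mgrid[0:h, 0:w]
    return np.hypot(rows - image.centre[0], cols - image.centre[1])


def circular_angle_difference(theta1, theta2):
    """Smallest arc between two angles in degrees; result in [0, 180]."""
    d = np.abs(np.asarray(theta1, dtype=np.float64) - np.asarray(theta2, dtype=np.float64)) % 360.0
    out = np.minimum(d, 360.0 - d)
    if np.isscalar(theta1) and np.isscalar(theta2):
        return float(out)
    return out


def read_image(path, radius_px: float | None = None,
               centre: tuple[float, float] | None = None) -> HemisphericalImage:
    """Read an 8-bit RGB PNG/TIFF as a :class:`HemisphericalImage`."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return HemisphericalImage.from_array(arr, radius_px=radius_px, centre=centre)


def write_image(image: HemisphericalImage, path) -> None:
    iio.imwrite(path, image.pixels)


def write_mask(image: HemisphericalImage, path) -> None:
    """Export the valid-pixel mask as a single-channel 0/255 PNG."""
    iio.imwrite(path, (image.valid_mask.astype(np.uint8) * 255))
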