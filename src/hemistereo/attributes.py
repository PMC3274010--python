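"""The six per-pixel matching attributes and their normalized differences.

Each candidate pixel is described by (a) the 3x3 window correlation
against its putative match, (b) texture (sample standard deviation of
the 3x3 intensity window), (c) raw RGB colour, (d) Sobel gradient
magnitude, (e) gradient direction and (f) the 8-neighbour Laplacian
magnitude.  Differences are normalized into [0, 1] with the fixed
attribute ranges: correlation [-1, 1], texture [0, 85], colour
[0, 765], gradient magnitude [0, 255], direction [0, 360] and Laplacian
[0, 2040].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import HemisphericalImage, circular_angle_difference, rgb_to_intensity

__all__ = [
    "ATTRIBUTE_KEYS",
    "TEXTURE_MAX",
    "COLOUR_MAX",
    "GRAD_MAG_MAX",
    "DIRECTION_DIVISOR",
    "LAPLACIAN_MAX",
    "AttributeVector",
    "AttributeDifference",
    "AttributePlanes",
    "window_correlation",
    "correlation_to_stack",
    "pixel_attributes",
    "attribute_difference",
]

#: canonical attribute order (a..f)
ATTRIBUTE_KEYS = ("correlation", "texture", "colour", "grad_mag", "grad_dir", "laplacian")

TEXTURE_MAX = 85.0
COLOUR_MAX = 765.0
GRAD_MAG_MAX = 255.0
DIRECTION_DIVISOR = 360.0
LAPLACIAN_MAX = 2040.0

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float64)
_LAPLACIAN = np.array([[-1, -1, -1], [-1, 8, -1], [-1, -1, -1]], dtype=np.float64)


@dataclass(frozen=True)
class AttributeVector:
    """Attributes of one pixel; the pair-dependent correlation slot may be None."""

    correlation_a: float | None
    texture_b: float
    colour_c: tuple[float, float, float]
    grad_mag_d: float
    grad_dir_e: float
    laplacian_f: float


@dataclass(frozen=True)
class AttributeDifference:
    """Normalized per-attribute differences, each in [0, 1], order a..f."""

    values: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        if any(not (0.0 <= v <= 1.0) for v in self.values):
            raise ValueError("normalized differences must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.float64)


class AttributePlanes:
    """Whole-image attribute planes with edge-replicated 3x3 windows.

    Precomputing the planes once per image makes per-candidate scoring a
    set of array lookups.  ``windows`` holds the flattened 3x3 intensity
    neighbourhood of every pixel (used for the pairwise correlation).
    """

    def __init__(self, image: HemisphericalImage):
        inten = rgb_to_intensity(image)
        pad = np.pad(inten, 1, mode="edge")
        win = np.lib.stride_tricks.sliding_window_view(pad, (3, 3))
        self.windows = win.reshape(*inten.shape, 9).astype(np.float64)

        # texture: sample std dev (divisor n-1 = 8) of the 3x3 window
        mean = self.windows.mean(axis=-1)
        ss = ((self.windows - mean[..., None]) ** 2).sum(axis=-1)
        self.texture = np.sqrt(ss / 8.0)

        gx = ndimage.correlate(inten, _SOBEL_X, mode="nearest")          # along +col
        gy = ndimage.correlate(inten, _SOBEL_X.T, mode="nearest")        # along +row
        self.grad_mag = np.minimum(np.hypot(gx, gy), GRAD_MAG_MAX)
        # direction in the centred math frame (row axis flipped)
        self.grad_dir = np.degrees(np.arctan2(-gy, gx)) % 360.0
        self.laplacian = np.abs(ndimage.correlate(inten, _LAPLACIAN, mode="nearest"))
        self.colour = image.pixels.astype(np.float64)
        self.intensity = inten

    def vector(self, pixel: tuple[int, int]) -> AttributeVector:
        r, c = pixel
        return AttributeVector(
            correlation_a=None,
            texture_b=float(self.texture[r, c]),
            colour_c=tuple(self.colour[r, c]),
            grad_mag_d=float(self.grad_mag[r, c]),
            grad_dir_e=float(self.grad_dir[r, c]),
            laplacian_f=float(self.laplacian[r, c]),
        )


def window_correlation(left_window, right_window) -> float:
    """Pearson correlation of two 3x3 windows; 0 if either is constant."""
    a = np.asarray(left_window, dtype=np.float64).ravel()
    b = np.asarray(right_window, dtype=np.float64).ravel()
    if a.shape != (9,) or b.shape != (9,):
        raise ValueError("windows must be 3x3")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip((a * b).sum() / (na * nb), -1.0, 1.0))


def correlation_to_stack(left_window: np.ndarray, right_windows: np.ndarray) -> np.ndarray:
    """Correlation of one window against an (m, 9) stack (vectorised)."""
    a = np.asarray(left_window, dtype=np.float64).ravel()
    B = np.asarray(right_windows, dtype=np.float64).reshape(-1, 9)
    a = a - a.mean()
    B = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((a * a).sum())
    nb = np.sqrt((B * B).sum(axis=1))
    denom = na * nb
    out = np.zeros(B.shape[0])
    nz = denom > 0
    out[nz] = (B[nz] @ a) / denom[nz]
    return np.clip(out, -1.0, 1.0)


def pixel_attributes(image: HemisphericalImage, pixel: tuple[int, int]) -> AttributeVector:
    """Attribute vector of one pixel (correlation slot left empty)."""
    return AttributePlanes(image).vector(pixel)


def attribute_difference(
    A_l: AttributeVector, A_i: AttributeVector, rho_li: float
) -> AttributeDifference:
    """Normalized differences of two attribute vectors.

    The pairwise correlation enters as the dissimilarity
    ``(1 - rho)/2`` (0 at perfect match, 1 at perfect anti-match); the
    colour difference sums the absolute channel differences; the
    gradient-direction difference is circular before division by 360.
    """
    d_a = (1.0 - rho_li) / 2.0
    d_b = abs(A_l.texture_b - A_i.texture_b) / TEXTURE_MAX
    d_c = sum(abs(h1 - h2) for h1, h2 in zip(A_l.colour_c, A_i.colour_c)) / COLOUR_MAX
    d_d = abs(A_l.grad_mag_d - A_i.grad_mag_d) / GRAD_MAG_MAX
    d_e = circular_angle_difference(A_l.grad_dir_e, A_i.grad_dir_e) / DIRECTION_DIVISOR
    d_f = abs(A_l.laplacian_f - A_i.laplacian_f) / LAPLACIAN_MAX
    vals = tuple(float(np.clip(v, 0.0, 1.0)) for v in (d_a, d_b, d_c, d_d, d_e, d_f))
    return AttributeDifference(values=vals)


def difference_stack(
    planes_l: AttributePlanes,
    pixel_l: tuple[int, int],
    planes_r: AttributePlanes,
    cand_rows: np.ndarray,
    cand_cols: np.ndarray,
) -> np.ndarray:
    """(m, 6) normalized differences of one left pixel vs m candidates."""
    r, c = pixel_l
    rho = correlation_to_stack(planes_l.windows[r, c], planes_r.windows[cand_rows, cand_cols])
    d = np.empty((rho.shape[0], 6))
    d[:, 0] = (1.0 - rho) / 2.0
    d[:, 1] = np.abs(planes_l.texture[r, c] - planes_r.texture[cand_rows, cand_cols]) / TEXTURE_MAX
    d[:, 2] = (
        np.abs(planes_l.colour[r, c][None, :] - planes_r.colour[cand_rows, cand_cols]).sum(axis=1)
        / COLOUR_MAX
    )
    d[:, 3] = (
        np.abs(planes_l.grad_mag[r, c] - planes_r.grad_mag[cand_rows, cand_cols]) / GRAD_MAG_MAX
    )
    d[:, 4] = (
        circular_angle_difference(planes_l.grad_dir[r, c], planes_r.grad_dir[cand_rows, cand_cols])
        / DIRECTION_DIVISOR
    )
    d[:, 5] = (
        np.abs(planes_l.laplacian[r, c] - planes_r.laplacian[cand_rows, cand_cols]) / LAPLACIAN_MAX
    )
    return np.clip(d, 0.0, 1.0)
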