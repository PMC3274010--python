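"""Equidistant fisheye projection and epipolar candidate search.

The stereo device takes two hemispherical images with parallel, vertical
optical axes separated by a baseline ``y12`` (metres) along the world
y-axis.  Under the equidistant (ideal, distortion-free) fisheye model
the radial image distance is proportional to the ray's incidence angle:

    alpha = (r / R) * (pi / 2),        r = (2 R / pi) * alpha,

where ``R`` is the image radius in pixels and ``alpha`` in [0, pi/2]
(rim of the disc = 90 deg incidence).  A pixel in the left image fixes a
ray; varying the unknown object distance ``d`` along that ray and
projecting each 3-D point into the right camera traces the epipolar
curve, yielding the list of match candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import centred_xy, rowcol_from_xy

__all__ = [
    "StereoGeometry",
    "RayAngles",
    "image_to_ray",
    "ray_to_world",
    "shift_baseline",
    "world_to_image2",
    "project_epipolar",
    "epipolar_candidates",
]


@dataclass
class StereoGeometry:
    """Stereo-rig parameters and the depth search range.

    ``d_min``/``d_max`` bound the object-distance sweep (metres) used to
    trace epipolar curves; ``n_depth_samples`` points are taken
    log-spaced so the fast-varying near field is sampled densely.
    """

    radius_px_R: float
    baseline_y12: float = 1.0
    d_min: float = 0.5
    d_max: float = 25.0
    n_depth_samples: int = 200

    def __post_init__(self) -> None:
        if self.baseline_y12 < 0:
            raise ValueError("baseline must be non-negative")
        if not (0 < self.d_min < self.d_max):
            raise ValueError("need 0 < d_min < d_max")
        if self.n_depth_samples < 2:
            raise ValueError("n_depth_samples must be >= 2")

    def depth_samples(self) -> np.ndarray:
        return np.geomspace(self.d_min, self.d_max, self.n_depth_samples)


@dataclass(frozen=True)
class RayAngles:
    """Incidence angle alpha in [0, pi/2] and azimuth beta in (-pi, pi]."""

    alpha: float
    beta_azimuth: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= np.pi / 2 + 1e-12):
            raise ValueError("alpha must lie in [0, pi/2]")
        if not (-np.pi - 1e-12 < self.beta_azimuth <= np.pi + 1e-12):
            raise ValueError("beta must lie in (-pi, pi]")


def image_to_ray(x_i1: float, y_i1: float, R: float) -> RayAngles:
    """Centred image coordinates (px) -> ray angles (equidistant model)."""
    r = float(np.hypot(x_i1, y_i1))
    if r > R * (1 + 1e-12):
        raise ValueError("point lies outside the image disc")
    alpha = (min(r, R) / R) * (np.pi / 2)
    beta = float(np.arctan2(y_i1, x_i1)) if r > 0 else 0.0
    return RayAngles(alpha=alpha, beta_azimuth=beta)


def ray_to_world(angles: RayAngles, d: float, d_max: float | None = None):
    """3-D point on the ray at horizontal distance ``d`` (metres).

    Returns ``(point, degenerate)``.  ``alpha = 0`` leaves the height
    unbounded; the point at ``d_max`` (or ``d``) along the optical axis
    is returned with ``degenerate = True``.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    a, b = angles.alpha, angles.beta_azimuth
    if a == 0.0:
        z = d_max if d_max is not None else d
        return np.array([0.0, 0.0, z]), True
    x1 = d * np.cos(b)
    y1 = d * np.sin(b)
    z1 = d / np.tan(a)
    return np.array([x1, y1, z1]), False


def shift_baseline(P1, y12: float) -> np.ndarray:
    """Express a point of camera-1's frame in camera-2's frame."""
    P1 = np.asarray(P1, dtype=np.float64)
    return P1 + np.array([0.0, y12, 0.0])


def world_to_image2(P2, R: float):
    """Project a 3-D point into centred image coordinates.

    Returns ``((x_i2, y_i2), imaged)``; ``imaged`` is False for points
    behind the hemisphere (incidence beyond 90 deg), whose coordinates
    are clamped to the rim.
    """
    X2, Y2, Z2 = np.asarray(P2, dtype=np.float64)
    rho = np.hypot(X2, Y2)
    if rho == 0.0 and Z2 == 0.0:
        raise ValueError("cannot project the camera origin")
    alpha2 = np.arctan2(rho, Z2)            # [0, pi]
    imaged = alpha2 <= np.pi / 2
    alpha2 = min(alpha2, np.pi / 2)
    r2 = (2.0 * R / np.pi) * alpha2
    beta2 = np.arctan2(Y2, X2) if rho > 0 else 0.0
    return (r2 * np.cos(beta2), r2 * np.sin(beta2)), bool(imaged)


def project_epipolar(x_i1, y_i1, geom: StereoGeometry, d_values=None):
    """Trace the epipolar curve of left pixel(s) in the right image.

    Vectorised over both pixels and depth samples.  ``x_i1``/``y_i1``
    may be scalars or 1-D arrays of n pixels; returns centred right
    image coordinates of shape (n, n_d) plus a validity mask (points
    imaged inside the right hemisphere).
    """
    x_i1 = np.atleast_1d(np.asarray(x_i1, dtype=np.float64))
    y_i1 = np.atleast_1d(np.asarray(y_i1, dtype=np.float64))
    d = geom.depth_samples() if d_values is None else np.asarray(d_values, dtype=np.float64)
    R = geom.radius_px_R

    r = np.hypot(x_i1, y_i1)
    alpha = (np.minimum(r, R) / R) * (np.pi / 2)
    beta = np.arctan2(y_i1, x_i1)

    # rays at alpha = 0 have unbounded height: treat as points on the axis
    with np.errstate(divide="ignore"):
        cot = np.where(alpha > 0, 1.0 / np.tan(np.where(alpha > 0, alpha, 1.0)), np.inf)

    X1 = np.cos(beta)[:, None] * d[None, :]
    Y1 = np.sin(beta)[:, None] * d[None, :]
    Z1 = cot[:, None] * d[None, :]
    Y2 = Y1 + geom.baseline_y12

    rho = np.hypot(X1, Y2)
    with np.errstate(invalid="ignore"):
        alpha2 = np.arctan2(rho, Z1)
    ok = np.isfinite(alpha2) & (alpha2 <= np.pi / 2)
    # alpha = 0 rays stay on the optical axis of both cameras only if the
    # baseline is zero; with a baseline they are projected normally above.
    axis = ~np.isfinite(Z1)
    alpha2 = np.where(axis, 0.0, alpha2)
    ok = ok | axis
    r2 = (2.0 * R / np.pi) * np.minimum(alpha2, np.pi / 2)
    beta2 = np.arctan2(Y2, X1)
    return r2 * np.cos(beta2), r2 * np.sin(beta2), ok


def _candidate_mask(right_labels) -> np.ndarray:
    if hasattr(right_labels, "candidate_mask"):
        return right_labels.candidate_mask()
    return np.asarray(right_labels, dtype=bool)


def epipolar_candidates(
    pixel_left: tuple[int, int],
    geom: StereoGeometry,
    right_labels,
    centre: tuple[float, float],
) -> list[tuple[int, int]]:
    """Ordered, duplicate-free list of right-image candidate pixels.

    ``right_labels`` is a segmentation label map (or boolean candidate
    mask); epipolar-trace pixels not labelled as matching candidates are
    dropped.  The list may be empty.
    """
    mask = _candidate_mask(right_labels)
    x1, y1 = centred_xy(pixel_left, centre)
    x2, y2, ok = project_epipolar(x1, y1, geom)
    rows, cols = rowcol_from_xy(x2[0], y2[0], centre)
    rows = np.rint(rows).astype(int)
    cols = np.rint(cols).astype(int)
    h, w = mask.shape
    out: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    for rr, cc, valid in zip(rows, cols, ok[0]):
        if not valid:
            continue
        key = (int(rr), int(cc))
        if key in seen:
            continue
        seen.add(key)
        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
            out.append(key)
    return out
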