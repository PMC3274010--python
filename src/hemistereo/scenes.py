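"""Synthetic hemispherical forest stereo pairs with per-pixel ground truth.

The generator renders the scene classes a zenith-pointing fisheye
camera sees in a pine stand: a blue-dominant homogeneous sky, a
green-dominant grass ring near the horizon (with a shaded sector),
high-variance leaf-canopy sectors, and tree trunks modelled as vertical
cylinders standing on the ground plane.  Both cameras share a vertical
optical axis; the second is displaced by the baseline along the world
y-axis, and everything is projected under the same equidistant fisheye
model the matcher assumes, so the analytic per-pixel correspondence and
polar-angle disparity are known exactly.

Trunk surfaces carry a cross-width illumination gradient (sun-side
bright, far side shaded) and a gentle bark banding along the height, so
the matching attributes have enough structure to disambiguate
candidates, while local contrast stays below the leaf gate.  Trunk
distances default to the near working area of a forest inventory rig
(a few metres around the device), where the polar-angle parallax
saturates the disparity-map range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging import HemisphericalImage, circular_angle_difference
from .matching import THETA_MAX_DEFAULT, DisparityMap
from .segmentation import (
    LABEL_CANDIDATE,
    LABEL_GRASS,
    LABEL_LEAF,
    LABEL_OUTSIDE,
    LABEL_SKY,
    TextureLabelMap,
)

__all__ = [
    "TrunkSpec",
    "SceneSpec",
    "GroundTruth",
    "generate_scene",
    "trunk_error_percentage",
    "training_samples",
    "default_scene",
]


@dataclass
class TrunkSpec:
    """A vertical cylindrical trunk: bearing, range and appearance."""

    azimuth_deg: float
    distance_m: float
    radius_m: float = 0.25
    height_m: float = 7.0
    colour: tuple[int, int, int] = (125, 98, 72)
    shade_amplitude: float = 0.08   # cross-width illumination gradient
    band_amplitude: float = 1.5     # bark banding, intensity levels
    band_period_m: float = 1.0

    def __post_init__(self) -> None:
        if not (0.5 <= self.distance_m <= 25.0):
            raise ValueError("trunk distance must lie in [0.5, 25] m")
        if self.radius_m <= 0 or self.height_m <= 0:
            raise ValueError("trunk radius and height must be positive")


@dataclass
class SceneSpec:
    """Scene layout, appearance distributions and camera parameters."""

    trunks: list[TrunkSpec]
    radius_px: float = 63.0
    image_size: int = 131
    baseline_y12: float = 1.0
    rng_seed: int = 0
    theta_max: float = THETA_MAX_DEFAULT
    sky_colour: tuple[int, int, int] = (135, 155, 235)
    sky_noise: float = 1.2
    grass_colour: tuple[int, int, int] = (72, 150, 58)
    grass_noise: float = 1.2
    grass_alpha_min_deg: float = 78.0
    grass_shade_sector: tuple[float, float] = (180.0, 300.0)
    grass_shade_factor: float = 0.55
    canopy_colour: tuple[int, int, int] = (60, 110, 50)
    canopy_amplitude: float = 60.0  # half peak-to-peak of the speckle
    canopy_sectors: tuple = ((55.0, 120.0), (195.0, 250.0), (320.0, 355.0))
    canopy_alpha_deg: tuple[float, float] = (12.0, 55.0)
    trunk_noise: float = 1.0

    def __post_init__(self) -> None:
        if not self.trunks:
            raise ValueError("at least one trunk is required")
        if 2 * self.canopy_amplitude < 100.0:
            raise ValueError("canopy speckle amplitude must span >= 100 intensity levels")


@dataclass
class GroundTruth:
    """Per-pixel texture labels, true trunk disparity and correspondence."""

    labels: TextureLabelMap
    true_disparity: np.ndarray        # degrees; NaN off the trunks
    corr_rows: np.ndarray             # right-image row of the true match (float)
    corr_cols: np.ndarray
    theta_max: float = THETA_MAX_DEFAULT

    def trunk_mask(self) -> np.ndarray:
        return np.isfinite(self.true_disparity)

    def disparity_map(self) -> DisparityMap:
        return DisparityMap(values=self.true_disparity.copy(), theta_max=self.theta_max)


def _in_sector(az_deg: np.ndarray, sector: tuple[float, float]) -> np.ndarray:
    lo, hi = sector
    az = az_deg % 360.0
    if lo <= hi:
        return (az >= lo) & (az <= hi)
    return (az >= lo) | (az <= hi)


def _trunk_hits(spec: SceneSpec, trunk: TrunkSpec, alpha, beta, cam_offset_y: float):
    """Ray/cylinder intersection for every pixel of one camera.

    Returns (hit mask, horizontal depth s, height z, signed cross-width
    coordinate in [-1, 1]).
    """
    phi = np.radians(trunk.azimuth_deg)
    ax = trunk.distance_m * np.cos(phi)
    ay = trunk.distance_m * np.sin(phi) + cam_offset_y
    ux, uy = np.cos(beta), np.sin(beta)
    t_along = ax * ux + ay * uy
    perp = ax * uy - ay * ux          # signed distance of axis from the ray
    w = trunk.radius_m
    hit = (np.abs(perp) <= w) & (t_along > 0) & (alpha > 0)
    s = np.where(hit, t_along - np.sqrt(np.maximum(w * w - perp * perp, 0.0)), np.inf)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(hit, s / np.tan(np.where(alpha > 0, alpha, 1.0)), np.inf)
    hit &= z <= trunk.height_m
    s = np.where(hit, s, np.inf)
    return hit, s, z, np.where(hit, perp / w, 0.0)


def _render(spec: SceneSpec, cam_offset_y: float, rng: np.random.Generator):
    """Render one camera; returns (image, category map, trunk depth s, height z)."""
    n = spec.image_size
    centre = ((n - 1) / 2.0, (n - 1) / 2.0)
    rows, cols = np.mgrid[0:n, 0:n]
    x = cols - centre[1]
    y = centre[0] - rows
    r = np.hypot(x, y)
    inside = r <= spec.radius_px
    alpha = np.minimum(r / spec.radius_px, 1.0) * (np.pi / 2)
    beta = np.arctan2(y, x)
    alpha_deg = np.degrees(alpha)
    az_deg = np.degrees(beta) % 360.0

    img = np.zeros((n, n, 3), dtype=np.float64)
    # category: 0 outside, 1 sky, 2 grass, 3 canopy, 4+ trunk index
    cat = np.zeros((n, n), dtype=np.int16)

    sky = inside.copy()
    grass = inside & (alpha_deg >= spec.grass_alpha_min_deg)
    canopy = np.zeros_like(inside)
    for sector in spec.canopy_sectors:
        canopy |= _in_sector(az_deg, sector)
    canopy &= inside & ~grass
    canopy &= (alpha_deg >= spec.canopy_alpha_deg[0]) & (alpha_deg <= spec.canopy_alpha_deg[1])
    sky &= ~grass & ~canopy

    img[sky] = spec.sky_colour
    img[sky] += rng.normal(0.0, spec.sky_noise, size=(int(sky.sum()), 3))
    cat[sky] = 1

    gcol = np.broadcast_to(np.asarray(spec.grass_colour, float), (int(grass.sum()), 3)).copy()
    shade = _in_sector(az_deg[grass], spec.grass_shade_sector)
    gcol[shade] *= spec.grass_shade_factor
    img[grass] = gcol + rng.normal(0.0, spec.grass_noise, size=gcol.shape)
    cat[grass] = 2

    amp = spec.canopy_amplitude
    speckle = rng.uniform(-amp, amp, size=(int(canopy.sum()), 1))
    img[canopy] = np.asarray(spec.canopy_colour, float) + speckle
    img[canopy] += rng.uniform(-15.0, 15.0, size=(int(canopy.sum()), 3))
    cat[canopy] = 3

    depth = np.full((n, n), np.inf)
    height = np.full((n, n), np.inf)
    for t_idx, trunk in enumerate(spec.trunks):
        hit, s, z, cross = _trunk_hits(spec, trunk, alpha, beta, cam_offset_y)
        hit &= inside
        closer = hit & (s < depth)
        if not np.any(closer):
            continue
        base = np.asarray(trunk.colour, float)
        factor = 1.0 + trunk.shade_amplitude * cross[closer]
        band = trunk.band_amplitude * np.sin(2.0 * np.pi * z[closer] / trunk.band_period_m)
        col = base[None, :] * factor[:, None] + band[:, None]
        col += rng.normal(0.0, spec.trunk_noise, size=col.shape)
        img[closer] = col
        depth[closer] = s[closer]
        height[closer] = z[closer]
        cat[closer] = 4 + t_idx

    img[~inside] = 0.0
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    image = HemisphericalImage(pixels=pixels, radius_px=spec.radius_px, centre=centre)
    return image, cat, depth, height, (alpha, beta)


def generate_scene(spec: SceneSpec):
    """Render the stereo pair and its analytic ground truth.

    Returns ``(left, right, truth)``.  The true disparity of a left
    trunk pixel is the polar-angle difference between the pixel and the
    projection of its 3-D surface point into the right camera, clipped
    to ``theta_max`` (the disparity-map range).
    """
    rng = np.random.default_rng(spec.rng_seed)
    rng_l, rng_r = rng.spawn(2)
    left, cat_l, depth_l, height_l, (alpha, beta) = _render(spec, 0.0, rng_l)
    right, cat_r, _, _, _ = _render(spec, spec.baseline_y12, rng_r)

    for t_idx in range(len(spec.trunks)):
        if not np.any(cat_l == 4 + t_idx) and not np.any(cat_r == 4 + t_idx):
            raise ValueError(f"trunk {t_idx} projects outside both image discs")

    n = spec.image_size
    labels = np.full((n, n), LABEL_OUTSIDE, dtype=np.uint8)
    labels[cat_l == 1] = LABEL_SKY
    labels[cat_l == 2] = LABEL_GRASS
    labels[cat_l == 3] = LABEL_LEAF
    labels[cat_l >= 4] = LABEL_CANDIDATE

    trunk = cat_l >= 4
    true_disp = np.full((n, n), np.nan)
    corr_rows = np.full((n, n), np.nan)
    corr_cols = np.full((n, n), np.nan)
    if np.any(trunk):
        s = depth_l[trunk]
        z = height_l[trunk]
        b = beta[trunk]
        X1 = s * np.cos(b)
        Y1 = s * np.sin(b)
        Y2 = Y1 + spec.baseline_y12
        rho = np.hypot(X1, Y2)
        alpha2 = np.arctan2(rho, z)
        alpha2 = np.minimum(alpha2, np.pi / 2)
        r2 = (2.0 * spec.radius_px / np.pi) * alpha2
        beta2 = np.arctan2(Y2, X1)
        theta_l = np.degrees(b) % 360.0
        theta_r = np.degrees(beta2) % 360.0
        dtheta = np.minimum(circular_angle_difference(theta_l, theta_r), spec.theta_max)
        true_disp[trunk] = dtheta
        centre = left.centre
        corr_rows[trunk] = centre[0] - r2 * np.sin(beta2)
        corr_cols[trunk] = centre[1] + r2 * np.cos(beta2)

    truth = GroundTruth(
        labels=TextureLabelMap(labels=labels),
        true_disparity=true_disp,
        corr_rows=corr_rows,
        corr_cols=corr_cols,
        theta_max=spec.theta_max,
    )
    return left, right, truth


def trunk_error_percentage(
    estimated: DisparityMap, truth: GroundTruth, tolerance: float = 0.5
) -> float:
    """Percentage of trunk pixels with a null or out-of-tolerance disparity."""
    mask = truth.trunk_mask()
    total = int(mask.sum())
    if total == 0:
        raise ValueError("ground truth contains no trunk pixels")
    if estimated.values.shape != truth.true_disparity.shape:
        raise ValueError("shape mismatch between estimate and ground truth")
    est = estimated.values[mask]
    ref = truth.true_disparity[mask]
    bad = ~np.isfinite(est) | (np.abs(est - ref) > tolerance)
    return 100.0 * float(bad.sum()) / total


def training_samples(
    image: HemisphericalImage,
    truth: GroundTruth,
    n_total: int = 2560,
    rng_seed: int = 0,
):
    """Draw labelled sky/grass RGB training samples from a rendered scene."""
    rng = np.random.default_rng(rng_seed)
    samples, labels = [], []
    per = n_total // 2
    for code, name in ((LABEL_SKY, "sky"), (LABEL_GRASS, "grass")):
        rows, cols = np.nonzero(truth.labels.labels == code)
        if rows.size == 0:
            raise ValueError(f"scene contains no {name} pixels to sample")
        idx = rng.choice(rows.size, size=min(per, rows.size), replace=rows.size < per)
        samples.append(image.pixels[rows[idx], cols[idx]].astype(np.float64))
        labels.extend([name] * idx.size)
    return np.concatenate(samples, axis=0), np.asarray(labels)


def default_scene(rng_seed: int = 0) -> SceneSpec:
    """The fixed-seed regression scene: three trunks in the near working area."""
    return SceneSpec(
        trunks=[
            TrunkSpec(azimuth_deg=25.0, distance_m=1.4, radius_m=0.22,
                      colour=(120, 95, 70)),
            TrunkSpec(azimuth_deg=150.0, distance_m=2.0, radius_m=0.28,
                      colour=(135, 105, 80)),
            TrunkSpec(azimuth_deg=305.0, distance_m=2.6, radius_m=0.25,
                      colour=(110, 88, 66)),
            # its right-image projection lands near the first trunk's
            # left-image bearing, so epipolar lists carry genuine
            # small-disparity false candidates the attributes must reject
            TrunkSpec(azimuth_deg=355.0, distance_m=2.2, radius_m=0.25,
                      colour=(100, 80, 60)),
        ],
        rng_seed=rng_seed,
    )
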