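"""Similarity scoring, match selection and disparity-map construction.

Per-attribute similarity is ``s_j = 1 - diff_j``.  The weighted fuzzy
similarity (WFS) of a candidate pair aggregates the six normalized
attribute differences as

    d(A_l, A_i) = (1/6) * sum_j (1 - w_j * |A_lj - A_ij|),

which spans [5/6, 1] (the weights sum to 1); the score is linearly
remapped to [0, 1].  The Yager aggregation baseline folds the six
per-attribute similarities pairwise with
``S = 1 - min(1, ((1-s_h)^p + (1-s_k)^p)^(1/p))``.

The best-scoring candidate is the unique match (uniqueness constraint,
left-to-right only), and the disparity of a matched pixel is the
absolute polar-angle difference |theta_l - theta_i| in degrees, clipped
to the map range [0, theta_max] with theta_max = 6.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import attributes as attr
from .geometry import StereoGeometry, project_epipolar
from .imaging import (
    HemisphericalImage,
    centred_xy,
    circular_angle_difference,
    polar_angle_map,
)
from .segmentation import TextureLabelMap

__all__ = [
    "THETA_MAX_DEFAULT",
    "DEFAULT_RELEVANCE",
    "WeightVector",
    "MatchDecision",
    "DisparityMap",
    "MatchTable",
    "single_similarity",
    "wfs_similarity",
    "yager_aggregate",
    "compute_weights",
    "best_match",
    "build_match_table",
    "disparity_from_table",
    "build_disparity_map",
]

THETA_MAX_DEFAULT = 6.0

#: relevance percentages (error rates of the single-attribute matchers on
#: reference trunk pixels) in the canonical attribute order a..f =
#: correlation, texture, colour, gradient magnitude, gradient direction,
#: Laplacian.  The reference relevances assign 12 to colour and 16 to
#: texture.
DEFAULT_RELEVANCE = (30.0, 16.0, 12.0, 10.0, 34.0, 30.0)

_METHODS = ("wfs", "yager") + attr.ATTRIBUTE_KEYS


@dataclass
class WeightVector:
    """Attribute weights w_j = p_j / sum(p), order a..f."""

    weights: np.ndarray
    relevance_percentages: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.shape != (6,):
            raise ValueError("six weights required")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if np.any(self.weights < 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in [0, 1]")


def compute_weights(relevance_percentages=DEFAULT_RELEVANCE) -> WeightVector:
    """Weights from relevance percentages: w_h = p_h / sum_k p_k."""
    p = np.asarray(relevance_percentages, dtype=np.float64)
    if p.shape != (6,):
        raise ValueError("six relevance percentages required")
    if np.any(p <= 0):
        raise ValueError("relevance percentages must be positive")
    return WeightVector(weights=p / p.sum(), relevance_percentages=p)


@dataclass
class MatchDecision:
    left_pixel: tuple[int, int]
    matched_right_pixel: tuple[int, int] | None
    score: float | None
    candidate_count: int


@dataclass
class DisparityMap:
    """Polar-angle disparity per pixel (degrees); NaN marks null entries."""

    values: np.ndarray
    theta_max: float = THETA_MAX_DEFAULT

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > self.theta_max + 1e-9):
            raise ValueError("disparities must lie in [0, theta_max]")

    def null_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def write_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.values.astype(np.float32))

    def write_preview_png(self, path) -> None:
        import imageio.v3 as iio

        scaled = np.where(
            np.isfinite(self.values), self.values / self.theta_max * 255.0, 0.0
        )
        iio.imwrite(path, scaled.astype(np.uint8))


def single_similarity(diff_j) -> float | np.ndarray:
    """s_j = 1 - diff_j for a normalized difference in [0, 1]."""
    d = np.asarray(diff_j, dtype=np.float64)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("differences must lie in [0, 1]")
    out = 1.0 - d
    return float(out) if np.isscalar(diff_j) else out


def wfs_similarity(diffs, w: WeightVector):
    """Raw and remapped weighted fuzzy similarity.

    ``diffs`` is a 6-vector (or (m, 6) stack) of normalized attribute
    differences; returns ``(raw, remapped)`` with raw in [5/6, 1] and
    remapped linearly rescaled to [0, 1].
    """
    d = np.asarray(diffs, dtype=np.float64)
    raw = (1.0 - w.weights * d).sum(axis=-1) / 6.0
    remapped = np.clip((raw - 5.0 / 6.0) * 6.0, 0.0, 1.0)
    return raw, remapped


def yager_aggregate(similarities, p: float = 2.0) -> float:
    """Left fold of the pairwise Yager union over per-attribute similarities."""
    if p < 1:
        raise ValueError("p must be >= 1")
    sims = list(np.asarray(similarities, dtype=np.float64).ravel())
    if not sims:
        raise ValueError("similarity list must be non-empty")
    s = sims[0]
    for t in sims[1:]:
        s = 1.0 - min(1.0, ((1.0 - s) ** p + (1.0 - t) ** p) ** (1.0 / p))
    return float(s)


def _score_stack(diffs: np.ndarray, method: str, weights: WeightVector, p: float) -> np.ndarray:
    """Score an (m, 6) difference stack under the chosen method."""
    if method == "wfs":
        return wfs_similarity(diffs, weights)[1]
    if method == "yager":
        sims = 1.0 - diffs
        return np.array([yager_aggregate(row, p) for row in sims])
    if method in attr.ATTRIBUTE_KEYS:
        j = attr.ATTRIBUTE_KEYS.index(method)
        return 1.0 - diffs[:, j]
    raise ValueError(f"unknown method '{method}' (choose from {_METHODS})")


def _select(scores: np.ndarray, abs_dtheta: np.ndarray) -> int:
    """Strict maximizer; ties broken by smaller |dtheta|, then list order."""
    best = scores.max()
    tied = np.where(scores >= best - 1e-12)[0]
    if tied.size == 1:
        return int(tied[0])
    return int(tied[np.argmin(abs_dtheta[tied])])


def best_match(
    left_pixel: tuple[int, int],
    candidates,
    left_image: HemisphericalImage,
    right_image: HemisphericalImage,
    weights: WeightVector | None = None,
    method: str = "wfs",
    p_exponent: float = 2.0,
) -> MatchDecision:
    """Score every epipolar candidate and apply the uniqueness rule."""
    weights = weights if weights is not None else compute_weights()
    candidates = list(candidates)
    if not candidates:
        return MatchDecision(left_pixel, None, None, 0)
    planes_l = attr.AttributePlanes(left_image)
    planes_r = attr.AttributePlanes(right_image)
    rows = np.array([c[0] for c in candidates])
    cols = np.array([c[1] for c in candidates])
    diffs = attr.difference_stack(planes_l, left_pixel, planes_r, rows, cols)
    scores = _score_stack(diffs, method, weights, p_exponent)
    theta = polar_angle_map(left_image)
    theta_r = polar_angle_map(right_image)
    dtheta = circular_angle_difference(theta[left_pixel], theta_r[rows, cols])
    k = _select(scores, dtheta)
    return MatchDecision(left_pixel, candidates[k], float(scores[k]), len(candidates))


@dataclass
class MatchTable:
    """Cached candidates and attribute differences for one stereo pair.

    Candidate search and attribute extraction dominate the cost of a
    matching run; caching them lets several scoring methods be compared
    on identical inputs.
    """

    shape: tuple[int, int]
    left_pixels: np.ndarray            # (n, 2) row/col of left candidates
    cand_rows: list[np.ndarray] = field(repr=False, default=None)
    cand_cols: list[np.ndarray] = field(repr=False, default=None)
    diffs: list[np.ndarray] = field(repr=False, default=None)
    abs_dtheta: list[np.ndarray] = field(repr=False, default=None)
    theta_max: float = THETA_MAX_DEFAULT


def build_match_table(
    left_image: HemisphericalImage,
    right_image: HemisphericalImage,
    left_labels: TextureLabelMap,
    right_labels: TextureLabelMap,
    geom: StereoGeometry,
    theta_max: float = THETA_MAX_DEFAULT,
) -> MatchTable:
    """Run the epipolar search and attribute extraction for all left candidates."""
    cand_mask_r = right_labels.candidate_mask()
    rows_l, cols_l = np.nonzero(left_labels.candidate_mask())
    planes_l = attr.AttributePlanes(left_image)
    planes_r = attr.AttributePlanes(right_image)
    theta_l = polar_angle_map(left_image)
    theta_r = polar_angle_map(right_image)

    x1 = cols_l - left_image.centre[1]
    y1 = left_image.centre[0] - rows_l
    x2, y2, ok = project_epipolar(x1, y1, geom)
    rr = np.rint(right_image.centre[0] - y2).astype(int)
    cc = np.rint(right_image.centre[1] + x2).astype(int)
    h, w = cand_mask_r.shape

    cand_rows, cand_cols, diffs, dthetas = [], [], [], []
    for i in range(rows_l.size):
        pts = np.stack([rr[i], cc[i]], axis=1)
        valid = ok[i] & (rr[i] >= 0) & (rr[i] < h) & (cc[i] >= 0) & (cc[i] < w)
        # deduplicate preserving depth order
        _, first = np.unique(pts, axis=0, return_index=True)
        keep = np.zeros(pts.shape[0], dtype=bool)
        keep[first] = True
        keep &= valid
        keep[keep] &= cand_mask_r[pts[keep, 0], pts[keep, 1]]
        idx = np.where(keep)[0]
        crow, ccol = pts[idx, 0], pts[idx, 1]
        cand_rows.append(crow)
        cand_cols.append(ccol)
        if idx.size:
            diffs.append(
                attr.difference_stack(planes_l, (rows_l[i], cols_l[i]), planes_r, crow, ccol)
            )
            dthetas.append(
                circular_angle_difference(theta_l[rows_l[i], cols_l[i]], theta_r[crow, ccol])
            )
        else:
            diffs.append(np.empty((0, 6)))
            dthetas.append(np.empty(0))
    return MatchTable(
        shape=(h, w),
        left_pixels=np.stack([rows_l, cols_l], axis=1) if rows_l.size else np.empty((0, 2), int),
        cand_rows=cand_rows,
        cand_cols=cand_cols,
        diffs=diffs,
        abs_dtheta=dthetas,
        theta_max=theta_max,
    )


def disparity_from_table(
    table: MatchTable,
    method: str = "wfs",
    weights: WeightVector | None = None,
    p_exponent: float = 2.0,
) -> DisparityMap:
    """Disparity map from cached candidates under the chosen scoring method."""
    weights = weights if weights is not None else compute_weights()
    values = np.full(table.shape, np.nan)
    for i, (r, c) in enumerate(table.left_pixels):
        diffs = table.diffs[i]
        if diffs.shape[0] == 0:
            continue
        scores = _score_stack(diffs, method, weights, p_exponent)
        k = _select(scores, table.abs_dtheta[i])
        values[r, c] = min(table.abs_dtheta[i][k], table.theta_max)
    return DisparityMap(values=values, theta_max=table.theta_max)


def build_disparity_map(
    left_image: HemisphericalImage,
    right_image: HemisphericalImage,
    left_labels: TextureLabelMap,
    right_labels: TextureLabelMap,
    geom: StereoGeometry,
    weights: WeightVector | None = None,
    method: str = "wfs",
    p_exponent: float = 2.0,
    theta_max: float = THETA_MAX_DEFAULT,
) -> DisparityMap:
    """Full matching stage: candidates, similarity, uniqueness, disparity.

    Excluded (leaf/sky/grass/outside) pixels and unmatched candidates
    carry the null marker.
    """
    table = build_match_table(left_image, right_image, left_labels, right_labels, geom, theta_max)
    return disparity_from_table(table, method=method, weights=weights, p_exponent=p_exponent)
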