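"""Texture segmentation of hemispherical forest images.

Forest scenes contain three textures that must not enter stereo
matching: leaves (high intensity contrast), sky (homogeneous,
blue-dominant) and grass (homogeneous, green-dominant, partially
shaded).  Two gates are applied in order:

1. a contrast gate: the normalized variance coefficient
   ``Z = 1 - 1/(1 + sigma^2)`` of the 3x3 intensity window exceeds a
   threshold ``T1`` -> leaf;
2. a colour classifier on chromatic coordinates ``(R, G, B)/(R+G+B)``
   combining a fuzzy c-means membership and a Gaussian maximum
   likelihood posterior with the *mean rule*; a pixel is labelled sky
   or grass only when the combined score clears ``T2``, otherwise it
   remains a matching candidate.

Chromatic normalization removes illumination magnitude so that shaded
and sunny grass land in the same cluster.  The fuzzy clustering is
trained unsupervised (with the pseudorandom centre initializer) and its
two clusters are identified with sky/grass by majority vote over the
labelled training samples; the Bayes model is trained supervised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.stats import multivariate_normal

from .imaging import HemisphericalImage, rgb_to_intensity

__all__ = [
    "LABEL_OUTSIDE",
    "LABEL_LEAF",
    "LABEL_SKY",
    "LABEL_GRASS",
    "LABEL_CANDIDATE",
    "LABEL_NAMES",
    "SegmentationParams",
    "FCModel",
    "PBModel",
    "TextureLabelMap",
    "chromatic_normalize",
    "chromatic_normalize_image",
    "contrast_coefficient",
    "contrast_map",
    "fc_init_centres",
    "fc_train",
    "fc_membership",
    "fc_objective",
    "pb_train",
    "pb_density",
    "classify_pixel",
    "segment_image",
    "train_models",
]

LABEL_OUTSIDE = 0
LABEL_LEAF = 1
LABEL_SKY = 2
LABEL_GRASS = 3
LABEL_CANDIDATE = 4
LABEL_NAMES = {
    LABEL_OUTSIDE: "outside",
    LABEL_LEAF: "leaf",
    LABEL_SKY: "sky",
    LABEL_GRASS: "grass",
    LABEL_CANDIDATE: "candidate",
}
#: canonical cluster order used by both classifiers
CLUSTER_TEXTURES = ("sky", "grass")


@dataclass
class SegmentationParams:
    """Thresholds and fuzzy-clustering hyper-parameters.

    ``T1`` gates the leaf/contrast test (on the 0-255 intensity scale a
    3x3 window with population variance above 4 exceeds Z = 0.8);
    ``T2`` gates the combined sky/grass score; ``exponent_weight_e`` is
    the fuzziness exponent of the c-means objective.
    """

    T1: float = 0.8
    T2: float = 0.8
    exponent_weight_e: float = 2.1
    epsilon_fc: float = 0.1
    k_max: int = 20
    n_clusters_c: int = 2
    contrast_window: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.T1 < 1 and 0 < self.T2 < 1):
            raise ValueError("T1 and T2 must lie in (0, 1)")
        if self.exponent_weight_e <= 1:
            raise ValueError("exponent weight must exceed 1")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.n_clusters_c != 2:
            raise ValueError("exactly two smooth-texture clusters are supported")
        if self.contrast_window % 2 != 1:
            raise ValueError("contrast window must be odd")


@dataclass
class FCModel:
    """Trained fuzzy c-means model: centres in chromatic space."""

    centres_v: np.ndarray               # (c, 3)
    memberships_mu: np.ndarray = None   # (n, c) training memberships
    exponent_weight_e: float = 2.1
    cluster_textures: tuple[str, ...] = CLUSTER_TEXTURES

    def __post_init__(self) -> None:
        self.centres_v = np.asarray(self.centres_v, dtype=np.float64)
        if not np.all(np.isfinite(self.centres_v)):
            raise ValueError("centres must be finite")


@dataclass
class PBModel:
    """Gaussian maximum-likelihood model per cluster."""

    means_v: np.ndarray        # (c, 3)
    covariances_C: np.ndarray  # (c, 3, 3)
    counts_n: np.ndarray       # (c,)
    cluster_textures: tuple[str, ...] = CLUSTER_TEXTURES

    def __post_init__(self) -> None:
        self.means_v = np.asarray(self.means_v, dtype=np.float64)
        self.covariances_C = np.asarray(self.covariances_C, dtype=np.float64)
        self.counts_n = np.asarray(self.counts_n, dtype=int)
        for C in self.covariances_C:
            if not np.allclose(C, C.T):
                raise ValueError("covariances must be symmetric")
        if np.any(self.counts_n < 2):
            raise ValueError("each cluster needs at least 2 samples")


@dataclass
class TextureLabelMap:
    """Per-pixel texture label on the {outside, leaf, sky, grass, candidate} alphabet."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)

    def candidate_mask(self) -> np.ndarray:
        return self.labels == LABEL_CANDIDATE

    def counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.labels == code)) for code, name in LABEL_NAMES.items()}

    def write_png(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, self.labels.astype(np.uint8))


def chromatic_normalize(rgb) -> np.ndarray:
    """(R, G, B) -> (R, G, B)/U with U = R+G+B; black maps to (1/3, 1/3, 1/3)."""
    v = np.asarray(rgb, dtype=np.float64)
    u = v.sum()
    if u == 0:
        return np.full(3, 1.0 / 3.0)
    return v / u


def chromatic_normalize_image(pixels: np.ndarray) -> np.ndarray:
    """Vectorised chromatic normalization of an (..., 3) RGB array."""
    v = np.asarray(pixels, dtype=np.float64)
    u = v.sum(axis=-1, keepdims=True)
    out = np.divide(v, u, out=np.full_like(v, 1.0 / 3.0), where=u > 0)
    return out


def contrast_coefficient(window) -> float:
    """Z = 1 - 1/(1 + sigma^2), population variance of the window's intensities."""
    w = np.asarray(window, dtype=np.float64)
    if w.size == 0:
        raise ValueError("window must be non-empty")
    var = float(np.var(w))
    return 1.0 - 1.0 / (1.0 + var)


def contrast_map(image: HemisphericalImage, window: int = 3) -> np.ndarray:
    """Per-pixel contrast coefficient Z over a sliding window (edge-replicated)."""
    inten = rgb_to_intensity(image)
    mean = ndimage.uniform_filter(inten, size=window, mode="nearest")
    mean_sq = ndimage.uniform_filter(inten * inten, size=window, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return 1.0 - 1.0 / (1.0 + var)


def _to_unit_interval(samples: np.ndarray):
    lo = samples.min(axis=0)
    span = samples.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    return (samples - lo) / safe, lo, span, safe


def fc_init_centres(samples, c: int, rng_seed: int = 0) -> np.ndarray:
    """Pseudorandom centre initializer.

    The samples are linearly mapped to [0, 1] per dimension (Y); with
    mean vector m and M = max|Y - m| the centres are drawn as
    ``v = 2 M * R + m`` with R uniform in [0, 1], then mapped back to
    the original sample space.  Degenerate dimensions (zero span) pin
    the centre at the mean.  Deterministic for a fixed seed.
    """
    samples = np.asarray(samples, dtype=np.float64)
    n, d = samples.shape
    if n < c:
        raise ValueError("need at least c samples")
    Y, lo, span, safe = _to_unit_interval(samples)
    m = Y.mean(axis=0)
    M = np.max(np.abs(Y - m), axis=0) if n else np.zeros(d)
    rng = np.random.default_rng(rng_seed)
    R = rng.random((c, d))
    vY = 2.0 * M[None, :] * R + m[None, :]
    v = vY * safe[None, :] + lo[None, :]
    v[:, span == 0] = samples[0, span == 0]
    return v


def _memberships(samples: np.ndarray, centres: np.ndarray, e: float) -> np.ndarray:
    """Fuzzy membership grades; a zero-distance sample gets a crisp row."""
    d2 = ((samples[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    mu = np.zeros((samples.shape[0], centres.shape[0]))
    zero = d2 <= 0.0
    any_zero = zero.any(axis=1)
    if np.any(any_zero):
        rows = np.where(any_zero)[0]
        cols = np.argmax(zero[rows], axis=1)
        mu[rows, cols] = 1.0
    rest = ~any_zero
    if np.any(rest):
        p = 2.0 / (e - 1.0)
        dist = np.sqrt(d2[rest])
        ratio = (dist[:, :, None] / dist[:, None, :]) ** p
        mu[rest] = 1.0 / ratio.sum(axis=2)
    return mu


def fc_objective(samples, centres, mu, e: float) -> float:
    """C-means objective sum_ij mu_ij^e * d_ij^2 (non-increasing across training)."""
    d2 = ((np.asarray(samples)[:, None, :] - np.asarray(centres)[None, :, :]) ** 2).sum(axis=2)
    return float((np.asarray(mu) ** e * d2).sum())


def fc_train(samples, params: SegmentationParams, init_centres=None) -> FCModel:
    """Unsupervised fuzzy c-means on chromatic samples.

    Alternates the membership and centre updates until the largest
    membership change falls below ``epsilon_fc`` or ``k_max`` passes.
    """
    samples = np.asarray(samples, dtype=np.float64)
    c, e = params.n_clusters_c, params.exponent_weight_e
    if samples.shape[0] < c:
        raise ValueError("need at least c samples")
    centres = (
        np.asarray(init_centres, dtype=np.float64)
        if init_centres is not None
        else fc_init_centres(samples, c, params.rng_seed)
    )
    mu = _memberships(samples, centres, e)
    for _ in range(params.k_max):
        w = mu**e
        denom = w.sum(axis=0)
        denom = np.where(denom > 0, denom, 1.0)
        centres = (w.T @ samples) / denom[:, None]
        mu_new = _memberships(samples, centres, e)
        delta = np.abs(mu_new - mu).max()
        mu = mu_new
        if delta < params.epsilon_fc:
            break
    return FCModel(centres_v=centres, memberships_mu=mu, exponent_weight_e=e)


def fc_membership(x, model: FCModel, e: float | None = None) -> np.ndarray:
    """Membership grades of one sample (or an (n, 3) batch) to the trained clusters."""
    e = model.exponent_weight_e if e is None else e
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    mu = _memberships(np.atleast_2d(x), model.centres_v, e)
    return mu[0] if single else mu


def pb_train(samples_per_cluster, ridge: float = 1e-6,
             cluster_textures: tuple[str, ...] = CLUSTER_TEXTURES) -> PBModel:
    """Gaussian ML estimates (mean, unbiased covariance) per cluster.

    Singular covariances are regularized by adding ``ridge * I``.
    """
    means, covs, counts = [], [], []
    for samples in samples_per_cluster:
        s = np.asarray(samples, dtype=np.float64)
        if s.shape[0] < 2:
            raise ValueError("each cluster needs at least 2 samples")
        mean = s.mean(axis=0)
        cov = np.cov(s, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        # chromatic coordinates sum to 1, so the raw covariance is rank
        # deficient; ridge until the density is well defined
        for _ in range(12):
            try:
                multivariate_normal(mean=mean, cov=cov)
                break
            except (np.linalg.LinAlgError, ValueError):
                cov = cov + ridge * np.eye(cov.shape[0])
                ridge *= 10.0
        means.append(mean)
        covs.append(cov)
        counts.append(s.shape[0])
    return PBModel(
        means_v=np.array(means),
        covariances_C=np.array(covs),
        counts_n=np.array(counts),
        cluster_textures=cluster_textures,
    )


def pb_density(x, mean, covariance) -> float | np.ndarray:
    """Multivariate normal density p(x | cluster)."""
    return multivariate_normal.pdf(x, mean=np.asarray(mean), cov=np.asarray(covariance))


def _pb_posterior(x: np.ndarray, pb: PBModel) -> np.ndarray:
    """Equal-prior cluster posterior P(c_j | x); vectorised over samples."""
    x = np.atleast_2d(x)
    logs = np.stack(
        [
            multivariate_normal.logpdf(x, mean=pb.means_v[j], cov=pb.covariances_C[j])
            for j in range(pb.means_v.shape[0])
        ],
        axis=-1,
    )
    logs = np.atleast_2d(logs)
    logs -= logs.max(axis=1, keepdims=True)
    p = np.exp(logs)
    return p / p.sum(axis=1, keepdims=True)


def classify_pixel(x, fc: FCModel, pb: PBModel, T2: float = 0.8) -> str:
    """Mean-rule combination of membership and posterior.

    ``m_j = 0.5 (mu_j + P_j)``; the pixel takes the argmax texture only
    under a strict win and ``m_j > T2``, otherwise it stays
    ``"unclassified"`` (a stereo-matching candidate).
    """
    mu = fc_membership(x, fc)
    post = _pb_posterior(np.asarray(x, dtype=np.float64), pb)[0]
    m = 0.5 * (mu + post)
    j = int(np.argmax(m))
    other = m[1 - j] if m.shape[0] == 2 else np.max(np.delete(m, j))
    if m[j] > other and m[j] > T2:
        return fc.cluster_textures[j]
    return "unclassified"


def segment_image(
    image: HemisphericalImage,
    params: SegmentationParams,
    fc: FCModel,
    pb: PBModel,
) -> TextureLabelMap:
    """Label every valid pixel as leaf, sky, grass or matching candidate.

    The contrast gate runs strictly first (leaves are excluded on
    texture alone); remaining valid pixels go through the combined
    colour classifier.
    """
    h, w = image.shape
    labels = np.full((h, w), LABEL_OUTSIDE, dtype=np.uint8)
    valid = image.valid_mask
    Z = contrast_map(image, params.contrast_window)
    leaf = valid & (Z > params.T1)
    labels[leaf] = LABEL_LEAF

    rest = valid & ~leaf
    if np.any(rest):
        x = chromatic_normalize_image(image.pixels[rest])
        mu = fc_membership(x, fc)
        post = _pb_posterior(x, pb)
        m = 0.5 * (mu + post)
        best = np.argmax(m, axis=1)
        best_m = m[np.arange(m.shape[0]), best]
        other_m = m[np.arange(m.shape[0]), 1 - best]
        decided = (best_m > other_m) & (best_m > params.T2)
        out = np.full(x.shape[0], LABEL_CANDIDATE, dtype=np.uint8)
        texture_codes = {"sky": LABEL_SKY, "grass": LABEL_GRASS}
        codes = np.array([texture_codes[t] for t in fc.cluster_textures], dtype=np.uint8)
        out[decided] = codes[best[decided]]
        labels[rest] = out
    return TextureLabelMap(labels=labels)


def train_models(samples, labels, params: SegmentationParams):
    """Train both classifiers from labelled (R, G, B) samples.

    ``labels`` hold the texture name ("sky"/"grass") per sample.  The
    fuzzy clustering runs unsupervised and its clusters are tied to
    textures by majority vote of the labelled samples; the Bayes model
    is estimated per texture.  Returned models share the canonical
    (sky, grass) cluster order.
    """
    samples = np.asarray(samples, dtype=np.float64)
    labels = np.asarray(labels)
    x = chromatic_normalize_image(samples)
    present = set(np.unique(labels).tolist())
    for texture in CLUSTER_TEXTURES:
        if texture not in present:
            raise ValueError(f"missing training samples for texture '{texture}'")

    fc = fc_train(x, params)
    # majority vote: which unsupervised cluster holds most sky samples
    assign = np.argmax(fc.memberships_mu, axis=1)
    sky_votes = np.bincount(assign[labels == "sky"], minlength=2)
    sky_cluster = int(np.argmax(sky_votes))
    order = [sky_cluster, 1 - sky_cluster]
    fc = FCModel(
        centres_v=fc.centres_v[order],
        memberships_mu=fc.memberships_mu[:, order],
        exponent_weight_e=fc.exponent_weight_e,
        cluster_textures=CLUSTER_TEXTURES,
    )
    pb = pb_train([x[labels == t] for t in CLUSTER_TEXTURES])
    return fc, pb
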