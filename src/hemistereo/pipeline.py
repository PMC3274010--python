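"""End-to-end pipeline: segmentation -> epipolar matching -> smoothing.

The stages run in the fixed order segment (both images) -> epipolar
candidate search + similarity/uniqueness matching -> disparity map ->
Hopfield smoothing, each consuming only prior-stage artifacts.  All
randomness is seeded, so a configuration reproduces its numeric
artifacts byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hopfield, matching, scenes, segmentation
from .geometry import StereoGeometry
from .imaging import HemisphericalImage, read_image

logger = logging.getLogger("hemistereo")

__all__ = ["PipelineConfig", "run_pipeline", "train_models_from_csv", "save_models", "load_models"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Either ``scene`` (a synthetic scene specification, which also
    provides training samples and ground truth) or the pair
    ``left_path``/``right_path`` plus ``training_csv`` must be given.
    """

    out_dir: str = "hemistereo_out"
    scene: scenes.SceneSpec | None = None
    left_path: str | None = None
    right_path: str | None = None
    radius_px: float | None = None
    training_csv: str | None = None
    seg_params: segmentation.SegmentationParams = field(
        default_factory=segmentation.SegmentationParams
    )
    geometry: StereoGeometry | None = None
    weights: matching.WeightVector | None = None
    method: str = "wfs"
    p_exponent: float = 2.0
    theta_max: float = matching.THETA_MAX_DEFAULT
    hnn_params: hopfield.HNNParams = field(default_factory=hopfield.HNNParams)
    error_tolerance_deg: float = 0.5
    rng_seed: int = 0


def train_models_from_csv(path, params: segmentation.SegmentationParams):
    """Train FC + PB models from CSV rows R,G,B,label."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    samples = df[["r", "g", "b"]].to_numpy(dtype=np.float64)
    labels = df["label"].astype(str).str.strip().to_numpy()
    return segmentation.train_models(samples, labels, params)


def save_models(fc: segmentation.FCModel, pb: segmentation.PBModel, path) -> None:
    """Serialize both models to a documented JSON text format."""
    payload = {
        "cluster_textures": list(fc.cluster_textures),
        "fc": {
            "centres_v": fc.centres_v.tolist(),
            "exponent_weight_e": fc.exponent_weight_e,
        },
        "pb": {
            "means_v": pb.means_v.tolist(),
            "covariances_C": pb.covariances_C.tolist(),
            "counts_n": pb.counts_n.tolist(),
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path):
    payload = json.loads(Path(path).read_text())
    textures = tuple(payload["cluster_textures"])
    fc = segmentation.FCModel(
        centres_v=np.asarray(payload["fc"]["centres_v"]),
        exponent_weight_e=payload["fc"]["exponent_weight_e"],
        cluster_textures=textures,
    )
    pb = segmentation.PBModel(
        means_v=np.asarray(payload["pb"]["means_v"]),
        covariances_C=np.asarray(payload["pb"]["covariances_C"]),
        counts_n=np.asarray(payload["pb"]["counts_n"]),
        cluster_textures=textures,
    )
    return fc, pb


def _load_pair(config: PipelineConfig):
    if config.scene is not None:
        left, right, truth = scenes.generate_scene(config.scene)
        return left, right, truth
    if not (config.left_path and config.right_path):
        raise ValueError("either a scene spec or both image paths are required")
    left = read_image(config.left_path, radius_px=config.radius_px)
    right = read_image(config.right_path, radius_px=config.radius_px)
    return left, right, None


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write every artifact to ``out_dir``.

    Returns a summary dict with per-stage counts, artifact paths and
    (for synthetic scenes) the trunk-pixel error percentages before and
    after smoothing.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    try:
        left, right, truth = _load_pair(config)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise RuntimeError(f"stage 'load' failed: {exc}") from exc
    logger.info("loaded stereo pair %s", left.shape)

    try:
        if truth is not None:
            samples, labels = scenes.training_samples(left, truth, rng_seed=config.rng_seed)
            fc, pb = segmentation.train_models(samples, labels, config.seg_params)
        elif config.training_csv:
            fc, pb = train_models_from_csv(config.training_csv, config.seg_params)
        else:
            raise ValueError("no training data: provide a scene or a training CSV")
        save_models(fc, pb, out / "models.json")
    except RuntimeError:
        raise
    except Exception as exc:
        raise RuntimeError(f"stage 'train' failed: {exc}") from exc

    try:
        labels_l = segmentation.segment_image(left, config.seg_params, fc, pb)
        labels_r = segmentation.segment_image(right, config.seg_params, fc, pb)
        labels_l.write_png(out / "left_labels.png")
        labels_r.write_png(out / "right_labels.png")
        summary["stages"]["segment"] = {
            "left": labels_l.counts(),
            "right": labels_r.counts(),
        }
        logger.info("segmentation: %s", summary["stages"]["segment"]["left"])
    except Exception as exc:
        raise RuntimeError(f"stage 'segment' failed: {exc}") from exc

    try:
        geom = config.geometry or StereoGeometry(
            radius_px_R=left.radius_px,
            baseline_y12=config.scene.baseline_y12 if config.scene else 1.0,
        )
        table = matching.build_match_table(
            left, right, labels_l, labels_r, geom, theta_max=config.theta_max
        )
        disparity = matching.disparity_from_table(
            table, method=config.method, weights=config.weights, p_exponent=config.p_exponent
        )
        disparity.write_tiff(out / "disparity_initial.tif")
        disparity.write_preview_png(out / "disparity_initial.png")
        matched = int(np.isfinite(disparity.values).sum())
        summary["stages"]["match"] = {
            "left_candidates": int(table.left_pixels.shape[0]),
            "matched": matched,
            "method": config.method,
        }
        logger.info("matching: %d/%d pixels matched", matched, table.left_pixels.shape[0])
    except Exception as exc:
        raise RuntimeError(f"stage 'match' failed: {exc}") from exc

    try:
        smoothed, state = hopfield.hnn_run(disparity, config.hnn_params)
        smoothed.write_tiff(out / "disparity_smoothed.tif")
        smoothed.write_preview_png(out / "disparity_smoothed.png")
        hopfield.write_energy_trace(state, out / "energy_trace.csv")
        summary["stages"]["smooth"] = {
            "iterations": state.iterations,
            "final_nc": state.changed_count_nc,
            "final_energy": state.energy_trace[-1] if state.energy_trace else None,
        }
        logger.info("smoothing: %d outer iterations", state.iterations)
    except Exception as exc:
        raise RuntimeError(f"stage 'smooth' failed: {exc}") from exc

    if truth is not None:
        metrics = {
            "error_initial_pct": scenes.trunk_error_percentage(
                disparity, truth, config.error_tolerance_deg
            ),
            "error_smoothed_pct": scenes.trunk_error_percentage(
                smoothed, truth, config.error_tolerance_deg
            ),
            "tolerance_deg": config.error_tolerance_deg,
        }
        summary["metrics"] = metrics
        logger.info(
            "trunk error: %.2f%% -> %.2f%%",
            metrics["error_initial_pct"],
            metrics["error_smoothed_pct"],
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    summary["out_dir"] = str(out)
    return summary
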