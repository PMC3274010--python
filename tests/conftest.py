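"""Shared fixtures: the fixed-seed regression scene and its pipeline run."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hemistereo import hopfield, matching, scenes, segmentation
from hemistereo.geometry import StereoGeometry

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

REGRESSION_SEED = 0
SINGLE_METHODS = ("correlation", "texture", "colour", "grad_mag", "grad_dir", "laplacian")


@pytest.fixture(scope="session")
def regression_scene():
    """Fixed-seed synthetic forest scene with analytic ground truth."""
    spec = scenes.default_scene(rng_seed=REGRESSION_SEED)
    left, right, truth = scenes.generate_scene(spec)
    return {"spec": spec, "left": left, "right": right, "truth": truth}


@pytest.fixture(scope="session")
def regression_models(regression_scene):
    samples, labels = scenes.training_samples(
        regression_scene["left"], regression_scene["truth"], rng_seed=REGRESSION_SEED
    )
    params = segmentation.SegmentationParams(rng_seed=REGRESSION_SEED)
    fc, pb = segmentation.train_models(samples, labels, params)
    return {"params": params, "fc": fc, "pb": pb, "samples": samples, "labels": labels}


@pytest.fixture(scope="session")
def regression_run(regression_scene, regression_models):
    """Full pipeline artifacts on the regression scene, all methods scored."""
    sc = regression_scene
    mdl = regression_models
    labels_l = segmentation.segment_image(sc["left"], mdl["params"], mdl["fc"], mdl["pb"])
    labels_r = segmentation.segment_image(sc["right"], mdl["params"], mdl["fc"], mdl["pb"])
    geom = StereoGeometry(
        radius_px_R=sc["left"].radius_px, baseline_y12=sc["spec"].baseline_y12
    )
    table = matching.build_match_table(sc["left"], sc["right"], labels_l, labels_r, geom)
    disparity = {
        m: matching.disparity_from_table(table, method=m)
        for m in ("wfs",) + SINGLE_METHODS
    }
    smoothed, state = hopfield.hnn_run(disparity["wfs"], hopfield.HNNParams())
    errors = {
        m: scenes.trunk_error_percentage(d, sc["truth"]) for m, d in disparity.items()
    }
    errors["hnn"] = scenes.trunk_error_percentage(smoothed, sc["truth"])
    return {
        **sc,
        "labels_l": labels_l,
        "labels_r": labels_r,
        "geom": geom,
        "table": table,
        "disparity": disparity,
        "smoothed": smoothed,
        "state": state,
        "errors": errors,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
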