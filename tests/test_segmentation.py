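"""Contrast gate, fuzzy clustering, Bayes estimator and the combined rule."""

import numpy as np
import pytest

from hemistereo import segmentation as seg
from hemistereo.imaging import HemisphericalImage


@pytest.fixture()
def params():
    return seg.SegmentationParams(rng_seed=7)


class TestChromaticNormalize:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((100, 100, 100), (1 / 3, 1 / 3, 1 / 3)),
            ((0, 0, 255), (0, 0, 1)),
            ((50, 100, 150), (1 / 6, 1 / 3, 1 / 2)),
            ((0, 0, 0), (1 / 3, 1 / 3, 1 / 3)),  # black-pixel convention
        ],
    )
    def test_values(self, rgb, expected):
        assert seg.chromatic_normalize(rgb) == pytest.approx(expected)

    def test_image_version_sums_to_one(self, rng):
        px = rng.integers(0, 256, size=(8, 8, 3))
        out = seg.chromatic_normalize_image(px)
        assert np.allclose(out.sum(axis=-1), 1.0)


class TestContrast:
    def test_constant_window_is_zero(self):
        assert seg.contrast_coefficient(np.full(9, 77)) == 0.0

    def test_variance_four_gives_point_eight(self):
        assert seg.contrast_coefficient([0, 4]) == pytest.approx(0.8)

    def test_extreme_window_close_to_one(self):
        z = seg.contrast_coefficient([0] + [255] * 8)
        assert z > 0.999


class TestFuzzyClustering:
    def test_init_identical_samples_collapse_to_mean(self):
        x = np.tile([0.2, 0.3, 0.5], (10, 1))
        v = seg.fc_init_centres(x, 2, rng_seed=0)
        assert np.allclose(v, x[0])

    def test_init_deterministic_and_bounded(self, rng):
        x = rng.random((50, 3))
        v1 = seg.fc_init_centres(x, 2, rng_seed=3)
        v2 = seg.fc_init_centres(x, 2, rng_seed=3)
        assert np.array_equal(v1, v2)
        m = x.mean(axis=0)
        M = np.abs(x - m).max(axis=0)
        assert np.all(v1 >= m - 2 * M - 1e-12) and np.all(v1 <= m + 2 * M + 1e-12)

    def test_recovers_two_blobs(self, params):
        rng = np.random.default_rng(42)
        a = rng.normal([0.1, 0.3, 0.6], 0.01, size=(100, 3))
        b = rng.normal([0.4, 0.4, 0.2], 0.01, size=(100, 3))
        model = seg.fc_train(np.vstack([a, b]), params)
        centres = model.centres_v[np.argsort(model.centres_v[:, 0])]
        assert np.all(np.abs(centres[0] - [0.1, 0.3, 0.6]) < 0.02)
        assert np.all(np.abs(centres[1] - [0.4, 0.4, 0.2]) < 0.02)

    def test_membership_rows_sum_to_one(self, params, rng):
        x = rng.random((60, 3))
        model = seg.fc_train(x, params)
        assert np.allclose(model.memberships_mu.sum(axis=1), 1.0)
        fresh = seg.fc_membership(rng.random((10, 3)), model)
        assert np.allclose(fresh.sum(axis=1), 1.0)

    def test_objective_non_increasing_over_iterations(self, rng):
        x = rng.random((80, 3))
        objs = []
        for k in range(1, 6):
            p = seg.SegmentationParams(rng_seed=5, k_max=k, epsilon_fc=1e-12)
            m = seg.fc_train(x, p)
            objs.append(seg.fc_objective(x, m.centres_v, m.memberships_mu, p.exponent_weight_e))
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_zero_distance_sample_is_crisp(self, params):
        model = seg.FCModel(centres_v=[[0.1, 0.2, 0.7], [0.5, 0.3, 0.2]])
        mu = seg.fc_membership([0.1, 0.2, 0.7], model)
        assert mu == pytest.approx([1.0, 0.0])

    def test_equidistant_sample_is_split(self):
        model = seg.FCModel(centres_v=[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        mu = seg.fc_membership([0.5, 0.0, 0.0], model)
        assert mu == pytest.approx([0.5, 0.5])

    def test_membership_from_distances_one_and_two(self):
        # distances (1, 2) with e = 2.1 -> mu_1 = 1/(1 + 0.5^(2/1.1))
        model = seg.FCModel(centres_v=[[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        mu = seg.fc_membership([1.0, 0.0, 0.0], model, e=2.1)
        expected = 1.0 / (1.0 + 0.5 ** (2 / 1.1))
        assert mu[0] == pytest.approx(expected, abs=1e-4)
        assert mu[0] == pytest.approx(0.779, abs=2e-3)


class TestBayes:
    def test_hand_example(self):
        model = seg.pb_train([[[0, 0, 0], [2, 2, 2]], [[0, 0, 1], [1, 0, 0]]])
        assert model.means_v[0] == pytest.approx([1, 1, 1])
        assert model.covariances_C[0] == pytest.approx(np.full((3, 3), 2.0), abs=1e-3)

    def test_single_sample_cluster_rejected(self):
        with pytest.raises(ValueError):
            seg.pb_train([[[1, 2, 3]], [[0, 0, 1], [1, 0, 0]]])

    def test_gaussian_recovery(self):
        rng = np.random.default_rng(11)
        mean = np.array([0.2, 0.5, 0.3])
        cov = np.array([[0.04, 0.01, 0.0], [0.01, 0.09, 0.0], [0.0, 0.0, 0.02]])
        x = rng.multivariate_normal(mean, cov, size=10_000)
        model = seg.pb_train([x, x[:100]])
        se = np.sqrt(np.diag(cov) / 10_000)
        assert np.all(np.abs(model.means_v[0] - mean) < 3 * se)
        assert np.allclose(model.covariances_C[0], cov, atol=0.01)

    def test_covariances_psd_after_training(self, rng):
        # includes degenerate clusters (rank-deficient chromatic samples)
        groups = [rng.random((40, 3)), seg.chromatic_normalize_image(rng.random((40, 3)))]
        model = seg.pb_train(groups)
        for C in model.covariances_C:
            assert np.allclose(C, C.T)
            assert np.linalg.eigvalsh(C).min() > -1e-12

    def test_density_closed_forms(self):
        peak = (2 * np.pi) ** -1.5
        assert seg.pb_density([0, 0, 0], [0, 0, 0], np.eye(3)) == pytest.approx(peak)
        assert seg.pb_density([1, 0, 0], [0, 0, 0], np.eye(3)) == pytest.approx(
            peak * np.exp(-0.5)
        )
        d1 = seg.pb_density([0.5, 0, 0], [0, 0, 0], np.eye(3))
        d2 = seg.pb_density([1.5, 0, 0], [0, 0, 0], np.eye(3))
        assert peak > d1 > d2


class TestCombinedRule:
    def _models(self):
        fc = seg.FCModel(centres_v=[[0.2, 0.3, 0.5], [0.3, 0.5, 0.2]])
        pb = seg.pb_train(
            [
                [[0.2, 0.3, 0.5], [0.21, 0.29, 0.5], [0.19, 0.31, 0.5]],
                [[0.3, 0.5, 0.2], [0.31, 0.49, 0.2], [0.29, 0.51, 0.2]],
            ]
        )
        return fc, pb

    def test_clear_sky_pixel(self):
        fc, pb = self._models()
        assert seg.classify_pixel([0.2, 0.3, 0.5], fc, pb, T2=0.8) == "sky"

    def test_tie_stays_unclassified(self):
        fc, pb = self._models()
        assert seg.classify_pixel([0.25, 0.4, 0.35], fc, pb, T2=0.8) == "unclassified"

    def test_mean_rule_below_threshold_unclassified(self):
        # mu = (0.9, 0.1), posterior = (0.6, 0.4) -> m = 0.75 < T2 = 0.8
        mu, post = np.array([0.9, 0.1]), np.array([0.6, 0.4])
        m = 0.5 * (mu + post)
        assert m[0] > m[1] and m[0] < 0.8


class TestSegmentImage:
    def test_constant_image_has_no_leaf(self, params, regression_models):
        img = HemisphericalImage.from_array(np.full((31, 31, 3), 128, dtype=np.uint8))
        out = seg.segment_image(img, params, regression_models["fc"], regression_models["pb"])
        assert not np.any(out.labels == seg.LABEL_LEAF)

    def test_checkerboard_region_is_all_leaf(self, params, regression_models):
        arr = np.zeros((31, 31, 3), dtype=np.uint8)
        arr[(np.indices((31, 31)).sum(axis=0) % 2) == 0] = 255
        img = HemisphericalImage.from_array(arr)
        out = seg.segment_image(img, params, regression_models["fc"], regression_models["pb"])
        assert np.all(out.labels[img.valid_mask] == seg.LABEL_LEAF)

    def test_labels_partition_the_disc(self, regression_run):
        labels = regression_run["labels_l"].labels
        valid = regression_run["left"].valid_mask
        assert np.all(labels[~valid] == seg.LABEL_OUTSIDE)
        assert np.all(labels[valid] != seg.LABEL_OUTSIDE)

    def test_sky_self_consistency(self, regression_run):
        """>= 95% of interior true-sky pixels recovered when trained on the
        scene itself.  The one-pixel region border is excluded: windows
        straddling a region boundary legitimately trip the contrast gate."""
        from scipy import ndimage

        truth = regression_run["truth"].labels.labels
        est = regression_run["labels_l"].labels
        sky = ndimage.binary_erosion(truth == seg.LABEL_SKY, np.ones((3, 3)))
        assert np.mean(est[sky] == seg.LABEL_SKY) >= 0.95

    def test_raising_t2_never_adds_sky_or_grass(self, regression_scene, regression_models):
        img = regression_scene["left"]
        counts = []
        for t2 in (0.6, 0.8, 0.95):
            p = seg.SegmentationParams(T2=t2, rng_seed=0)
            out = seg.segment_image(img, p, regression_models["fc"], regression_models["pb"])
            counts.append(
                int(np.sum((out.labels == seg.LABEL_SKY) | (out.labels == seg.LABEL_GRASS)))
            )
        assert counts[0] >= counts[1] >= counts[2]


class TestTrainModels:
    def test_cluster_identity_by_majority_vote(self, regression_models):
        fc, pb = regression_models["fc"], regression_models["pb"]
        assert fc.cluster_textures == ("sky", "grass")
        # sky centre must be blue-dominant, grass centre green-dominant
        assert fc.centres_v[0][2] == max(fc.centres_v[0])
        assert fc.centres_v[1][1] == max(fc.centres_v[1])
        assert pb.means_v[0][2] == max(pb.means_v[0])

    def test_missing_texture_rejected(self, params, rng):
        x = rng.integers(0, 255, size=(20, 3))
        with pytest.raises(ValueError, match="grass"):
            seg.train_models(x, np.array(["sky"] * 20), params)
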