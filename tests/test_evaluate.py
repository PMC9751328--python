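"""Accuracy, cross-validation aggregation, CAMs and heatmaps."""

import numpy as np
import pytest

from semssl import nn
from semssl.downstream import BinaryClassifier, ProbeConfig, train_binary_head
from semssl.evaluate import (EvalReport, LabelOracle, accuracy,
                             class_distribution_heatmap, cross_validate,
                             format_report_table, generate_cam, heatmap_table)
from semssl.patches import MultiLabel, derive_labels, extract_patches, grid_shape
from semssl.ssl import AugmentPolicy, PretrainConfig, init_state
from semssl.types import ClassLabel, CLASS_ORDER


class TestAccuracy:
    def test_basic_ratio(self):
        pred = [1] * 9 + [0]
        truth = [1] * 10
        assert accuracy(pred, truth) == 0.9

    def test_perfect_and_inverted(self):
        assert accuracy([0, 1, 1], [0, 1, 1]) == 1.0
        assert accuracy([1, 0, 0], [0, 1, 1]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy([], [])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        pred = rng.integers(0, 2, 50)
        truth = rng.integers(0, 2, 50)
        perm = rng.permutation(50)
        assert accuracy(pred, truth) == accuracy(pred[perm], truth[perm])


class TestCrossValidate:
    def _constant_pipeline(self, train_idx, test_idx, seed):
        pred = np.ones((len(test_idx), 3), bool)
        truth = np.ones((len(test_idx), 3), bool)
        truth[: len(test_idx) // 2, 0] = False
        return pred, truth

    def test_constant_pipeline_zero_overall_variance(self):
        report = cross_validate(self._constant_pipeline, n_items=40, folds=10,
                                seed=1)
        assert report.overall[1] == 0.0
        assert report.per_class["cell"] == (100.0, 0.0)

    def test_report_echoes_provenance(self):
        report = cross_validate(self._constant_pipeline, n_items=40, folds=10,
                                seed=123, config_echo={"note": "x"})
        assert report.folds == 10
        assert report.seed == 123
        assert report.n_repeats == 10
        assert report.config_echo == {"note": "x"}

    def test_matches_hand_rolled_fold_loop(self):
        rng_master = np.random.default_rng(7)
        table = rng_master.integers(0, 2, (30, 3)).astype(bool)

        def pipeline(train_idx, test_idx, seed):
            rng = np.random.default_rng(seed)
            pred = rng.integers(0, 2, (len(test_idx), 3)).astype(bool)
            return pred, table[test_idx]

        report = cross_validate(pipeline, n_items=30, folds=5, seed=11)

        # independent loop over the same derived splits
        rng = np.random.default_rng(11)
        per_class = []
        for _ in range(5):
            order = rng.permutation(30)
            test_idx = order[:6]
            seed_r = int(rng.integers(0, 2 ** 31))
            pred, truth = pipeline(order[6:], test_idx, seed_r)
            per_class.append([(pred[:, j] == truth[:, j]).mean()
                              for j in range(3)])
        arr = np.array(per_class) * 100
        for j, name in enumerate(("byproduct", "cell", "surface")):
            assert np.isclose(report.per_class[name][0], arr[:, j].mean())
            assert np.isclose(report.per_class[name][1],
                              arr[:, j].std(ddof=1))

    def test_kfold_scheme_uses_each_item_once(self):
        seen = []

        def pipeline(train_idx, test_idx, seed):
            seen.extend(test_idx.tolist())
            return (np.ones((len(test_idx), 3), bool),
                    np.ones((len(test_idx), 3), bool))

        cross_validate(pipeline, n_items=20, folds=4, seed=2, scheme="kfold")
        assert sorted(seen) == list(range(20))

    def test_insufficient_items_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            cross_validate(self._constant_pipeline, n_items=5, folds=10, seed=0)


class TestEvalReport:
    def test_overall_must_be_mean_of_per_class(self):
        with pytest.raises(ValueError, match="overall"):
            EvalReport(per_class={"byproduct": (90.0, 1.0),
                                  "cell": (80.0, 1.0),
                                  "surface": (70.0, 1.0)},
                       overall=(85.0, 1.0), n_repeats=10, protocol="linear",
                       folds=10, seed=0)

    def test_published_row_arithmetic_is_consistent(self):
        # mean-of-per-class convention reproduces a known table row
        report = EvalReport(per_class={"byproduct": (88.32, 0.74),
                                       "cell": (91.04, 0.51),
                                       "surface": (96.21, 0.03)},
                            overall=((88.32 + 91.04 + 96.21) / 3, 0.42),
                            n_repeats=10, protocol="linear", folds=10, seed=0)
        assert abs(report.overall[0] - 91.857) < 1e-2
        table = format_report_table({"supervised": report})
        assert "91.86" in table and "Overall" in table


class TestCAM:
    def _trained_corner_model(self):
        rng = np.random.default_rng(3)
        patches, labels = [], []
        for i in range(40):
            arr = rng.uniform(0.0, 0.25, (32, 32))
            if i % 2 == 0:
                arr[2:12, 2:12] += 0.7          # bright object top-left
            patches.append(arr)
            labels.append(MultiLabel(byproduct=False, cell=bool(i % 2 == 0),
                                     surface=True))
        state = init_state("noncontrastive", PretrainConfig(
            encoder_channels=(4, 8), projector_hidden=16, projector_dim=8,
            seed=1))
        cfg = ProbeConfig(mode="finetune", label_fraction=1.0, epochs=25,
                          lr=0.1, seed=2,
                          augment=AugmentPolicy(output_size=32,
                                                crop_scale=(1.0, 1.0),
                                                flip_prob=0.0))
        clf = train_binary_head(state, patches, labels, ClassLabel.CELL, cfg)
        return clf, patches

    def test_cam_shape_and_range(self):
        clf, patches = self._trained_corner_model()
        cam = generate_cam(clf, patches[0])
        assert cam.shape == patches[0].shape
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_uniform_feature_maps_give_uniform_cam(self, monkeypatch):
        clf, patches = self._trained_corner_model()

        class ConstMaps:
            out_dim = clf.encoder.out_dim

            def eval(self):
                return self

            def forward(self, x):
                from semssl.nn import Tensor
                return Tensor(np.full((1, self.out_dim, 4, 4), 0.3))

        monkeypatch.setattr(clf, "encoder", ConstMaps())
        cam = generate_cam(clf, np.full((32, 32), 0.5))
        assert np.allclose(cam, cam.flat[0])

    def test_cam_mass_concentrates_on_object_quadrant(self):
        clf, patches = self._trained_corner_model()
        cam = generate_cam(clf, patches[0])        # object in top-left
        total = cam.sum()
        top_left = cam[:16, :16].sum()
        assert top_left / total >= 0.5

    def test_model_without_feature_maps_rejected(self):
        class NoMaps:
            pass

        with pytest.raises(TypeError, match="feature maps"):
            generate_cam(NoMaps(), np.zeros((16, 16)))


class TestHeatmap:
    def test_oracle_heatmap_equals_per_patch_labels(self, small_image):
        kernel, stride = 32, 16
        hms = class_distribution_heatmap(small_image, LabelOracle(0.01),
                                         kernel, stride)
        patches = extract_patches(small_image, kernel, stride)
        rows, cols = grid_shape(*small_image.pixels.shape, kernel, stride)
        for label in CLASS_ORDER:
            assert hms[label].grid.shape == (rows, cols)
        for idx, p in enumerate(patches):
            lab = derive_labels(p.annotation, 0.01)
            r, c = idx // cols, idx % cols
            assert hms[ClassLabel.BYPRODUCT].grid[r, c] == lab.byproduct
            assert hms[ClassLabel.CELL].grid[r, c] == lab.cell
            assert hms[ClassLabel.SURFACE].grid[r, c] == lab.surface

    def test_all_surface_scene_under_oracle(self, flat_image):
        hms = class_distribution_heatmap(flat_image, LabelOracle(0.01), 16, 16)
        assert hms[ClassLabel.SURFACE].grid.all()
        assert not hms[ClassLabel.CELL].grid.any()
        assert not hms[ClassLabel.BYPRODUCT].grid.any()

    def test_heatmap_table_long_format(self, flat_image):
        hms = class_distribution_heatmap(flat_image, LabelOracle(0.01), 32, 32)
        table = heatmap_table(hms)
        assert set(table.columns) == {"row", "col", "class", "value"}
        assert len(table) == 3 * hms[ClassLabel.SURFACE].grid.size
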