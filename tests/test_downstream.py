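"""Binary-relevance protocol contracts and prediction merging."""

import hashlib

import numpy as np
import pytest

from semssl import nn
from semssl.downstream import (BinaryClassifier, MultiLabelPrediction,
                               ProbeConfig, predict_batch, predict_multilabel,
                               train_binary_head, train_supervised_baseline)
from semssl.patches import MultiLabel
from semssl.ssl import AugmentPolicy, PretrainConfig, init_state
from semssl.types import ClassLabel, CLASS_ORDER


def _state(seed=0):
    return init_state("noncontrastive", PretrainConfig(
        encoder_channels=(4, 8), projector_hidden=16, projector_dim=8,
        seed=seed))


def _labeled_set(n=40, m=32, seed=0):
    """Patches whose cell label follows a bright blob in the corner."""
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for i in range(n):
        arr = rng.uniform(0.0, 0.3, (m, m))
        positive = i % 2 == 0
        if positive:
            arr[4:16, 4:16] += 0.6
        patches.append(arr)
        labels.append(MultiLabel(byproduct=bool(i % 3 == 0), cell=positive,
                                 surface=bool(i % 5 != 0)))
    return patches, labels


def _params_digest(module: nn.Module) -> str:
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(p.data.tobytes())
    return h.hexdigest()


def _probe(mode="linear_frozen", **kw):
    kw.setdefault("augment", AugmentPolicy(output_size=32))
    kw.setdefault("label_fraction", 1.0)
    kw.setdefault("epochs", 5)
    return ProbeConfig(mode=mode, **kw)


class TestTrainBinaryHead:
    def test_linear_frozen_leaves_encoder_bit_identical(self):
        state = _state()
        patches, labels = _labeled_set()
        before = _params_digest(state.encoder)
        train_binary_head(state, patches, labels, ClassLabel.CELL, _probe())
        assert _params_digest(state.encoder) == before

    def test_finetune_does_not_mutate_pretrained_state(self):
        state = _state()
        patches, labels = _labeled_set()
        before = _params_digest(state.encoder)
        clf = train_binary_head(state, patches, labels, ClassLabel.CELL,
                                _probe("finetune"))
        assert _params_digest(state.encoder) == before
        assert _params_digest(clf.encoder) != before   # the copy trained

    def test_label_fraction_subsamples_training_set(self, monkeypatch):
        seen = {}
        import semssl.downstream as ds

        real = ds._train

        def spy(encoder, head, patches, y, *a, **kw):
            seen["n"] = len(patches)
            return real(encoder, head, patches, y, *a, **kw)

        monkeypatch.setattr(ds, "_train", spy)
        patches, labels = _labeled_set(n=40)
        train_binary_head(_state(), patches, labels, ClassLabel.CELL,
                          _probe(label_fraction=0.1, epochs=1))
        assert seen["n"] == 4

    def test_single_class_labeled_set_names_class(self):
        patches, labels = _labeled_set()
        labels = [MultiLabel(l.byproduct, l.cell, True) for l in labels]
        with pytest.raises(ValueError, match="surface"):
            train_binary_head(_state(), patches, labels, ClassLabel.SURFACE,
                              _probe())

    def test_separable_data_reaches_high_training_accuracy(self):
        patches, labels = _labeled_set(n=60)
        clf = train_binary_head(_state(), patches, labels, ClassLabel.CELL,
                                _probe("finetune", epochs=20, lr=0.1))
        scores = clf.scores(patches)
        pred = scores >= 0.5
        truth = np.array([l.cell for l in labels])
        assert (pred == truth).mean() >= 0.9


class TestPredict:
    def _fixed_models(self, scores):
        class Fixed(BinaryClassifier):
            def __init__(self, value):
                self.value = value
                self.input_mode = "original"
                self.output_size = 8

            def scores(self, patches, chunk=256):  # noqa: D102
                return np.full(len(patches), self.value)

        return {c: Fixed(s) for c, s in zip(CLASS_ORDER, scores)}

    def test_thresholding_of_scores(self):
        models = self._fixed_models((0.9, 0.2, 0.8))
        pred = predict_multilabel(models, np.zeros((8, 8)), threshold=0.5)
        assert pred.decisions == (True, False, True)
        assert pred.scores == (0.9, 0.2, 0.8)

    def test_empty_label_set_is_allowed(self):
        models = self._fixed_models((0.1, 0.2, 0.3))
        pred = predict_multilabel(models, np.zeros((8, 8)), threshold=0.5)
        assert pred.decisions == (False, False, False)
        assert pred.as_multilabel().any is False

    def test_missing_head_rejected(self):
        models = self._fixed_models((0.9, 0.2, 0.8))
        del models[ClassLabel.CELL]
        with pytest.raises(KeyError, match="CELL"):
            predict_batch(models, [np.zeros((8, 8))])


class TestSupervisedBaseline:
    def test_deterministic_given_seed(self):
        patches, labels = _labeled_set(n=24)
        cfg = _probe("finetune", epochs=2, seed=9)
        m1 = train_supervised_baseline(patches, labels, cfg, (4, 8))
        m2 = train_supervised_baseline(patches, labels, cfg, (4, 8))
        for c in CLASS_ORDER:
            np.testing.assert_array_equal(m1[c].scores(patches[:5]),
                                          m2[c].scores(patches[:5]))

    def test_returns_one_model_per_class(self):
        patches, labels = _labeled_set(n=24)
        models = train_supervised_baseline(patches, labels,
                                           _probe("finetune", epochs=1), (4, 8))
        assert set(models) == set(CLASS_ORDER)


def test_prediction_table_has_score_columns():
    from semssl.downstream import prediction_table
    preds = [MultiLabelPrediction(decisions=(True, False, True),
                                  scores=(0.9, 0.2, 0.8))]
    table = prediction_table([np.zeros((8, 8))], preds)
    assert {"byproduct", "cell", "surface", "byproduct_score",
            "cell_score", "surface_score"} <= set(table.columns)
    assert table.loc[0, "cell"] == 0 and table.loc[0, "cell_score"] == 0.2
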