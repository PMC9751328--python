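"""Binary-relevance multi-label classification on learned representations.

The K-class multi-label problem (K=3: byproduct, cell, surface) is split
into K independent binary classifiers sharing the pretrained encoder. Two
protocols:

* ``linear_frozen`` — only a linear head is trained on the frozen encoder's
  pooled features (linear probe; measures representation quality).
* ``finetune`` — encoder and head are updated jointly on the small labeled
  subset, with the encoder stepped at a tenth of the head's learning rate
  so the pretrained representation is refined rather than overwritten.

Per-class decisions are merged without any mutual exclusion: a patch may
carry one, two, all three, or — below threshold — no labels.

Class imbalance (surface is present in nearly every patch, byproduct in
far fewer) is handled by inverse-frequency weighting of the positive term
in the binary cross-entropy, on by default.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .nn import Tensor
from .patches import MultiLabel, Patch, make_object_masks
from .ssl import AugmentPolicy, EncoderState, _as_float_patch, _one_view, center_crop
from .types import ClassLabel, CLASS_NAMES, CLASS_ORDER

__all__ = [
    "ProbeConfig", "MultiLabelPrediction", "BinaryClassifier",
    "train_binary_head", "predict_multilabel", "predict_batch",
    "train_supervised_baseline", "prediction_table",
]


@dataclass
class ProbeConfig:
    mode: str = "linear_frozen"          # or "finetune"
    label_fraction: float = 0.10
    epochs: int = 20
    folds: int = 10
    seed: int = 0
    lr: float = 0.05
    sgd_momentum: float = 0.9
    batch_size: int = 64
    decision_threshold: float = 0.5
    class_weighting: bool = True
    input_mode: str = "original"          # or "masked" (ablation)
    encoder_lr_scale: float = 0.1         # finetune: encoder lr = scale * lr
    augment: AugmentPolicy = field(default_factory=AugmentPolicy)

    def validate(self) -> None:
        if self.mode not in ("linear_frozen", "finetune"):
            raise ValueError(f"unknown probe mode {self.mode!r}")
        if not 0.0 < self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.input_mode not in ("original", "masked"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class MultiLabelPrediction:
    """Per-class decisions and sigmoid scores in (byproduct, cell, surface)
    order; decisions are independent thresholdings of the scores."""

    decisions: Tuple[bool, bool, bool]
    scores: Tuple[float, float, float]

    def as_multilabel(self) -> MultiLabel:
        return MultiLabel(*[bool(d) for d in self.decisions])


class BinaryClassifier:
    """One encoder + linear head deciding presence of a single class."""

    def __init__(self, encoder: nn.ConvEncoder, head: nn.Linear,
                 target_class: ClassLabel, output_size: int,
                 input_mode: str = "original"):
        self.encoder = encoder
        self.head = head
        self.target_class = target_class
        self.output_size = output_size
        self.input_mode = input_mode

    def _input_array(self, patch: Union[Patch, np.ndarray]) -> np.ndarray:
        if self.input_mode == "masked" and isinstance(patch, Patch):
            patch = make_object_masks(patch)[self.target_class].pixels
        return center_crop(patch, self.output_size)

    def scores(self, patches: Sequence[Union[Patch, np.ndarray]],
               chunk: int = 256) -> np.ndarray:
        """Sigmoid presence scores for each patch (eval-time center crop)."""
        self.encoder.eval()
        views = np.stack([self._input_array(p) for p in patches])[:, None]
        out = []
        for start in range(0, len(views), chunk):
            feats = self.encoder.features(Tensor(views[start:start + chunk]))
            out.append(self.head(feats).sigmoid().data[:, 0])
        return np.concatenate(out)


def _labels_array(labels: Sequence[Union[MultiLabel, np.ndarray]]) -> np.ndarray:
    rows = [lab.as_array() if isinstance(lab, MultiLabel) else np.asarray(lab, bool)
            for lab in labels]
    return np.stack(rows)


def _subsample(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    k = max(1, int(round(fraction * n)))
    return rng.choice(n, size=k, replace=False)


def _class_column(target_class: ClassLabel) -> int:
    return CLASS_ORDER.index(target_class)


def _train(encoder: nn.ConvEncoder, head: nn.Linear,
           patches: Sequence[Union[Patch, np.ndarray]], y: np.ndarray,
           cfg: ProbeConfig, train_encoder: bool, encoder_lr: float,
           target_class: ClassLabel) -> None:
    """Shared SGD loop over augmented views with weighted BCE."""
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, int(target_class), 21]))
    pos = int(y.sum())
    # inverse-frequency weighting for rare positives only: a majority-
    # positive class (surface is present in nearly every patch) is never
    # down-weighted, and the boost is capped to keep the loss well scaled
    pos_weight = (float(np.clip((len(y) - pos) / pos, 1.0, 5.0))
                  if (cfg.class_weighting and pos) else 1.0)
    if train_encoder:
        encoder.train()
    else:
        # frozen probe: eval mode keeps normalization statistics (and thus
        # the whole encoder state) bit-identical and features deterministic
        encoder.eval()
    head_opt = nn.SGD(head.parameters(), lr=cfg.lr, momentum=cfg.sgd_momentum)
    enc_opt = (nn.SGD(encoder.parameters(), lr=encoder_lr,
                      momentum=cfg.sgd_momentum) if train_encoder else None)
    if cfg.input_mode == "masked":
        patches = [make_object_masks(p)[target_class].pixels
                   if isinstance(p, Patch) else p for p in patches]
    arrays = [_as_float_patch(p) for p in patches]
    n = len(arrays)
    bs = min(cfg.batch_size, n)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            if len(idx) < 2:
                continue
            views = np.stack([_one_view(arrays[i], cfg.augment, rng)
                              for i in idx])[:, None]
            x = Tensor(views)
            feats = (encoder.features(x) if train_encoder
                     else Tensor(encoder.features(x).data))
            logits = head(feats)
            loss = nn.bce_with_logits(logits, y[idx][:, None], pos_weight)
            head_opt.zero_grad()
            if enc_opt:
                enc_opt.zero_grad()
            loss.backward()
            head_opt.step()
            if enc_opt:
                enc_opt.step()


def train_binary_head(encoder_state: EncoderState,
                      labeled_patches: Sequence[Union[Patch, np.ndarray]],
                      labels: Sequence[MultiLabel],
                      target_class: ClassLabel,
                      cfg: Optional[ProbeConfig] = None) -> BinaryClassifier:
    """Train one per-class binary classifier under the configured protocol.

    ``linear_frozen`` leaves the pretrained encoder bit-identical and uses
    it read-only; ``finetune`` works on a private copy so the pretrained
    state itself also survives unchanged.
    """
    cfg = cfg or ProbeConfig()
    cfg.validate()
    y_all = _labels_array(labels)[:, _class_column(target_class)].astype(float)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, int(target_class), 20]))
    sel = _subsample(len(labeled_patches), cfg.label_fraction, rng)
    y = y_all[sel]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            f"labeled set contains a single class for "
            f"{CLASS_NAMES[_class_column(target_class)]}: cannot train a "
            f"binary classifier")
    subset = [labeled_patches[i] for i in sel]
    train_encoder = cfg.mode == "finetune"
    encoder = (copy.deepcopy(encoder_state.encoder) if train_encoder
               else encoder_state.encoder)
    if train_encoder:
        for _, p in encoder.named_parameters():
            p.requires_grad = True
    head = nn.Linear(encoder.out_dim, 1, rng=np.random.default_rng(
        np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, int(target_class), 22])))
    _train(encoder, head, subset, y, cfg, train_encoder,
           encoder_lr=cfg.encoder_lr_scale * cfg.lr, target_class=target_class)
    return BinaryClassifier(encoder, head, target_class,
                            cfg.augment.output_size, cfg.input_mode)


def predict_multilabel(models: Dict[ClassLabel, BinaryClassifier],
                       patch: Union[Patch, np.ndarray],
                       threshold: float = 0.5) -> MultiLabelPrediction:
    """Merge the three independent binary decisions for one patch."""
    preds = predict_batch(models, [patch], threshold)
    return preds[0]


def predict_batch(models: Dict[ClassLabel, BinaryClassifier],
                  patches: Sequence[Union[Patch, np.ndarray]],
                  threshold: float = 0.5) -> List[MultiLabelPrediction]:
    missing = [c for c in CLASS_ORDER if c not in models]
    if missing:
        raise KeyError(f"missing classifier heads for {[c.name for c in missing]}")
    scores = np.stack([models[c].scores(patches) for c in CLASS_ORDER], axis=1)
    out = []
    for row in scores:
        decisions = tuple(bool(s >= threshold) for s in row)
        out.append(MultiLabelPrediction(decisions=decisions,
                                        scores=tuple(float(s) for s in row)))
    return out


def prediction_table(patches: Sequence[Patch],
                     predictions: Sequence[MultiLabelPrediction]):
    """Label-table layout of predictions with per-class score columns."""
    import pandas as pd

    rows = []
    for p, pred in zip(patches, predictions):
        origin = p.origin if isinstance(p, Patch) else (-1, -1)
        rows.append({
            "source_id": getattr(p, "source_id", ""),
            "row": origin[0], "col": origin[1],
            "kernel": getattr(p, "m", np.asarray(p).shape[0]
                              if not isinstance(p, Patch) else p.m),
            "byproduct": int(pred.decisions[0]),
            "cell": int(pred.decisions[1]),
            "surface": int(pred.decisions[2]),
            "byproduct_score": pred.scores[0],
            "cell_score": pred.scores[1],
            "surface_score": pred.scores[2],
        })
    return pd.DataFrame(rows)


def train_supervised_baseline(labeled_patches: Sequence[Union[Patch, np.ndarray]],
                              labels: Sequence[MultiLabel],
                              cfg: Optional[ProbeConfig] = None,
                              encoder_channels: Tuple[int, ...] = (8, 16, 32, 64),
                              ) -> Dict[ClassLabel, BinaryClassifier]:
    """Three binary classifiers trained from random initialization.

    Same architecture, augmentations and (weighted) cross-entropy as the
    self-supervised probes, but with no pretraining: the comparator that
    quantifies what representation learning buys.
    """
    cfg = cfg or ProbeConfig(mode="finetune")
    cfg.validate()
    models: Dict[ClassLabel, BinaryClassifier] = {}
    for target_class in CLASS_ORDER:
        col = _class_column(target_class)
        y_all = _labels_array(labels)[:, col].astype(float)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, int(target_class), 30]))
        sel = _subsample(len(labeled_patches), cfg.label_fraction, rng)
        y = y_all[sel]
        if y.sum() == 0 or y.sum() == len(y):
            raise ValueError(
                f"labeled set contains a single class for {CLASS_NAMES[col]}: "
                f"cannot train a binary classifier")
        subset = [labeled_patches[i] for i in sel]
        init_rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, int(target_class), 31]))
        encoder = nn.ConvEncoder(encoder_channels, rng=init_rng)
        head = nn.Linear(encoder.out_dim, 1, rng=init_rng)
        _train(encoder, head, subset, y, cfg, train_encoder=True,
               encoder_lr=cfg.lr, target_class=target_class)
        models[target_class] = BinaryClassifier(
            encoder, head, target_class, cfg.augment.output_size, cfg.input_mode)
    return models
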