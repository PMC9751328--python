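"""Accuracy scoring, repeated cross-validation, CAMs and class heatmaps.

Accuracy is the plain correct/total ratio; for the multi-label task every
(patch, class) decision counts as one prediction, and the *overall* figure
reported alongside the per-class accuracies is the arithmetic mean of the
three per-class accuracies, computed per repeat and then aggregated as
mean +- sample standard deviation over the cross-validation repeats.

Class activation maps follow the global-average-pooling construction: the
map is the head-weighted sum of the final convolutional feature maps,
upsampled to the patch and min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .downstream import BinaryClassifier, predict_batch
from .patches import MultiLabel, Patch, derive_labels, extract_patches, grid_shape
from .types import AnnotatedImage, ClassLabel, CLASS_NAMES, CLASS_ORDER

__all__ = [
    "EvalReport", "ClassHeatmap", "LabelOracle", "accuracy",
    "cross_validate", "generate_cam", "class_distribution_heatmap",
    "format_report_table",
]


def accuracy(predictions: Sequence, truths: Sequence) -> float:
    """Number of correct predictions over total predictions."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    if pred.shape != true.shape:
        raise ValueError(f"prediction shape {pred.shape} != truth shape {true.shape}")
    return float((pred == true).mean())


@dataclass
class EvalReport:
    """Per-class and overall accuracy (percent) over CV repeats."""

    per_class: Dict[str, Tuple[float, float]]   # name -> (mean, std), percent
    overall: Tuple[float, float]
    n_repeats: int
    protocol: str
    folds: int
    seed: int
    config_echo: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mean_of_means = float(np.mean([m for m, _ in self.per_class.values()]))
        if abs(mean_of_means - self.overall[0]) > 1e-9:
            raise ValueError("overall mean must equal the mean of the "
                             "per-class means")
        for m, _ in (*self.per_class.values(), self.overall):
            if not 0.0 <= m <= 100.0:
                raise ValueError("accuracies must lie in [0, 100]")

    def to_dict(self) -> Dict:
        return {
            "per_class": {k: {"mean": m, "std": s}
                          for k, (m, s) in self.per_class.items()},
            "overall": {"mean": self.overall[0], "std": self.overall[1]},
            "n_repeats": self.n_repeats, "protocol": self.protocol,
            "folds": self.folds, "seed": self.seed,
            "config": self.config_echo,
        }


# pipeline_fn(train_idx, test_idx, repeat_seed) -> (pred (M,3), truth (M,3))
PipelineFn = Callable[[np.ndarray, np.ndarray, int],
                      Tuple[np.ndarray, np.ndarray]]


def cross_validate(pipeline_fn: PipelineFn, n_items: int, folds: int = 10,
                   seed: int = 0, protocol: str = "linear",
                   scheme: str = "repeated_split",
                   config_echo: Optional[Dict] = None) -> EvalReport:
    """Run ``folds`` train/test evaluations and aggregate accuracies.

    ``repeated_split`` (default) draws a fresh random split per repeat with
    a 1/folds test share; ``kfold`` runs classic k-fold with each fold once
    as the test set. Deterministic given ``seed``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n_items < folds:
        raise ValueError(f"{n_items} items cannot support {folds} folds")
    if scheme not in ("repeated_split", "kfold"):
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    per_class_acc: List[List[float]] = []
    overall_acc: List[float] = []
    if scheme == "kfold":
        order = rng.permutation(n_items)
        fold_sets = np.array_split(order, folds)
    for r in range(folds):
        if scheme == "repeated_split":
            order = rng.permutation(n_items)
            n_test = max(1, n_items // folds)
            test_idx, train_idx = order[:n_test], order[n_test:]
        else:
            test_idx = fold_sets[r]
            train_idx = np.concatenate([f for i, f in enumerate(fold_sets)
                                        if i != r])
        repeat_seed = int(rng.integers(0, 2 ** 31))
        pred, truth = pipeline_fn(train_idx, test_idx, repeat_seed)
        pred, truth = np.asarray(pred, bool), np.asarray(truth, bool)
        accs = [accuracy(pred[:, j], truth[:, j]) for j in range(pred.shape[1])]
        per_class_acc.append(accs)
        overall_acc.append(float(np.mean(accs)))
    arr = np.array(per_class_acc) * 100.0
    ov = np.array(overall_acc) * 100.0
    sd = (lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0)
    per_class = {name: (float(arr[:, j].mean()), sd(arr[:, j]))
                 for j, name in enumerate(CLASS_NAMES)}
    return EvalReport(per_class=per_class,
                      overall=(float(ov.mean()), sd(ov)),
                      n_repeats=folds, protocol=protocol, folds=folds,
                      seed=seed, config_echo=config_echo or {})


def format_report_table(reports: Dict[str, EvalReport]) -> str:
    """Human-readable table: rows = method, columns = classes + overall."""
    header = f"{'Method':<22}" + "".join(
        f"{name.capitalize():>18}" for name in CLASS_NAMES) + f"{'Overall':>18}"
    lines = [header, "-" * len(header)]
    for method, rep in reports.items():
        cells = [f"{m:.2f} ± {s:.2f}" for m, s in rep.per_class.values()]
        cells.append(f"{rep.overall[0]:.2f} ± {rep.overall[1]:.2f}")
        lines.append(f"{method:<22}" + "".join(f"{c:>18}" for c in cells))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# class activation maps
# ---------------------------------------------------------------------------

def generate_cam(model: BinaryClassifier,
                 patch: Union[Patch, np.ndarray]) -> np.ndarray:
    """Class-evidence map over the patch pixels, min-max scaled to [0, 1]."""
    encoder = getattr(model, "encoder", None)
    if encoder is None or not hasattr(encoder, "forward"):
        raise TypeError("model does not expose convolutional feature maps")
    arr = patch.pixels if isinstance(patch, Patch) else np.asarray(patch)
    encoder.eval()
    view = model._input_array(patch)[None, None]
    from .nn import Tensor
    fmaps = encoder.forward(Tensor(view)).data[0]          # (C, h, w)
    if fmaps.ndim != 3:
        raise TypeError("encoder output has no spatial feature maps")
    weights = model.head.weight.data[:, 0]                 # (C,)
    cam = np.tensordot(weights, fmaps, axes=(0, 0))        # (h, w)
    cam = sktransform.resize(cam, arr.shape, order=1, mode="reflect",
                             anti_aliasing=False, preserve_range=True)
    lo, hi = cam.min(), cam.max()
    if hi - lo < 1e-12:
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# spatial class-distribution heatmaps
# ---------------------------------------------------------------------------

@dataclass
class ClassHeatmap:
    """Per-class value over the sliding-window patch grid."""

    grid: np.ndarray            # (rows, cols)
    kernel: int
    stride: int
    class_label: ClassLabel
    value_kind: str             # "decision" or "score"


class LabelOracle:
    """Perfect model: decisions read off the ground-truth annotation."""

    def __init__(self, min_fraction: float = 0.01):
        self.min_fraction = min_fraction

    def predict(self, patches: Sequence[Patch]) -> np.ndarray:
        return np.stack([derive_labels(p.annotation, self.min_fraction).as_array()
                         for p in patches])


def class_distribution_heatmap(
        img: AnnotatedImage,
        models: Union[Dict[ClassLabel, BinaryClassifier], LabelOracle],
        kernel: int, stride: int, threshold: float = 0.5,
        value_kind: str = "decision") -> Dict[ClassLabel, ClassHeatmap]:
    """One grid per class over all sliding-window origins of ``img``."""
    patches = extract_patches(img, kernel, stride)
    rows, cols = grid_shape(*img.pixels.shape, kernel, stride)
    if isinstance(models, LabelOracle):
        values = models.predict(patches).astype(float)
    else:
        preds = predict_batch(models, patches, threshold)
        if value_kind == "decision":
            values = np.array([p.decisions for p in preds], dtype=float)
        else:
            values = np.array([p.scores for p in preds], dtype=float)
    out = {}
    for j, label in enumerate(CLASS_ORDER):
        out[label] = ClassHeatmap(grid=values[:, j].reshape(rows, cols),
                                  kernel=kernel, stride=stride,
                                  class_label=label, value_kind=value_kind)
    return out


def heatmap_table(heatmaps: Dict[ClassLabel, ClassHeatmap]) -> pd.DataFrame:
    """Long-format table (row, col, class, value) for export."""
    rows = []
    for label, hm in heatmaps.items():
        for (r, c), v in np.ndenumerate(hm.grid):
            rows.append({"row": r * hm.stride, "col": c * hm.stride,
                         "class": CLASS_NAMES[CLASS_ORDER.index(label)],
                         "value": v})
    return pd.DataFrame(rows)


def save_heatmap_png(heatmaps: Dict[ClassLabel, ClassHeatmap],
                     img: AnnotatedImage, path: str) -> None:
    """Side-by-side overlay figure: image + one panel per class."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, axes = plt.subplots(1, 4, figsize=(16, 4))
    axes[0].imshow(img.pixels, cmap="gray")
    axes[0].set_title(img.source_id)
    for ax, label in zip(axes[1:], CLASS_ORDER):
        hm = heatmaps[label]
        ax.imshow(img.pixels, cmap="gray")
        up = np.kron(hm.grid, np.ones((hm.stride, hm.stride)))
        ax.imshow(up, cmap="magma", alpha=0.45, vmin=0, vmax=1,
                  extent=(0, up.shape[1], up.shape[0], 0))
        ax.set_title(label.name.capitalize())
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=90)
    plt.close(fig)
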