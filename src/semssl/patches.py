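"""Sliding-window patch extraction, object masks, multi-labels and splits.

An image is decomposed into overlapping m x m patches by a sliding window
with a fixed stride. For every patch three *object masks* are derived from
the pixel-level annotation — one per class, keeping source intensity where
the annotation equals the target class and black elsewhere — and the
image-level multi-label is the triple of per-class presence flags. From
that point on, classifiers consume the original patch and its multi-label;
the masks serve auditing and label derivation only (a config switch in the
downstream stage allows masked-patch input for ablation).

Data budget: 80% of patches for representation learning, 10% for
fine-tuning, 10% for testing, by default sampled patch-wise; a
``spatial_block`` strategy is available that assigns contiguous source
regions to splits so overlapping windows never straddle the
labeled/unlabeled boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AnnotatedImage, ClassLabel, CLASS_NAMES, CLASS_ORDER

__all__ = [
    "Patch", "MaskedPatch", "MultiLabel", "SplitPlan",
    "extract_patches", "make_object_masks", "derive_labels",
    "split_dataset", "label_table", "save_patches",
]


@dataclass
class Patch:
    """An m x m window of a source image, with its annotation window."""

    pixels: np.ndarray       # (m, m) uint8
    annotation: np.ndarray   # (m, m) class codes
    origin: Tuple[int, int]  # (row, col) in source coordinates
    source_id: str
    m: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.annotation = np.asarray(self.annotation)
        if self.pixels.shape != self.annotation.shape:
            raise ValueError("patch pixels and annotation must align")
        if not self.m:
            self.m = self.pixels.shape[0]


@dataclass
class MaskedPatch:
    """Per-class rendering: target-class pixels keep intensity, rest black."""

    pixels: np.ndarray
    target_class: ClassLabel
    parent: Patch


@dataclass(frozen=True)
class MultiLabel:
    """Binary presence flags in canonical (byproduct, cell, surface) order."""

    byproduct: bool
    cell: bool
    surface: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.byproduct, self.cell, self.surface], dtype=bool)

    @property
    def any(self) -> bool:
        return self.byproduct or self.cell or self.surface


@dataclass
class SplitPlan:
    """Representation-learning / fine-tune / test budget."""

    repr_fraction: float = 0.80
    finetune_fraction: float = 0.10
    test_fraction: float = 0.10
    strategy: str = "random_patch"   # or "spatial_block"
    seed: int = 0
    folds: int = 10

    def validate(self) -> None:
        total = self.repr_fraction + self.finetune_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1.0, got {total}")
        if min(self.repr_fraction, self.finetune_fraction, self.test_fraction) < 0:
            raise ValueError("split fractions must be non-negative")
        if self.strategy not in ("random_patch", "spatial_block"):
            raise ValueError(f"unknown split strategy {self.strategy!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def extract_patches(img: AnnotatedImage, kernel: int, stride: int) -> List[Patch]:
    """All in-bounds sliding windows at origins (i*stride, j*stride).

    The patch count is (floor((H-k)/s)+1) * (floor((W-k)/s)+1).
    """
    H, W = img.pixels.shape
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if kernel > min(H, W):
        raise ValueError(f"kernel {kernel} exceeds image dimensions {(H, W)}")
    patches = []
    for r in range(0, H - kernel + 1, stride):
        for c in range(0, W - kernel + 1, stride):
            patches.append(Patch(pixels=img.pixels[r:r + kernel, c:c + kernel],
                                 annotation=img.annotation[r:r + kernel, c:c + kernel],
                                 origin=(r, c), source_id=img.source_id, m=kernel))
    return patches


def grid_shape(height: int, width: int, kernel: int, stride: int) -> Tuple[int, int]:
    """Rows/cols of the patch grid produced by :func:`extract_patches`."""
    return ((height - kernel) // stride + 1, (width - kernel) // stride + 1)


def make_object_masks(patch: Patch) -> Dict[ClassLabel, MaskedPatch]:
    """One masked rendering per class; supports partition the patch."""
    if patch.pixels.shape != patch.annotation.shape:
        raise ValueError("patch pixels and annotation are misaligned")
    masks = {}
    for label in CLASS_ORDER:
        pixels = np.where(patch.annotation == int(label), patch.pixels, 0)
        masks[label] = MaskedPatch(pixels=pixels.astype(patch.pixels.dtype),
                                   target_class=label, parent=patch)
    return masks


def derive_labels(ann_patch: np.ndarray, min_fraction: float = 0.01) -> MultiLabel:
    """Presence flags: class pixel fraction >= ``min_fraction``.

    ``min_fraction=0`` means a single pixel suffices. The default 1%
    suppresses stray single-pixel annotations while keeping genuinely
    mixed patches multi-labeled.
    """
    if not 0.0 <= min_fraction < 1.0:
        raise ValueError("min_fraction must lie in [0, 1)")
    ann_patch = np.asarray(ann_patch)
    total = ann_patch.size
    flags = {}
    for name, label in zip(CLASS_NAMES, CLASS_ORDER):
        count = int((ann_patch == int(label)).sum())
        present = count >= 1 if min_fraction == 0 else count / total >= min_fraction
        flags[name] = bool(present)
    return MultiLabel(**flags)


def _windows_overlap(p: Patch, q: Patch) -> bool:
    if p.source_id != q.source_id:
        return False
    (r1, c1), (r2, c2) = p.origin, q.origin
    return (r1 < r2 + q.m and r2 < r1 + p.m and c1 < c2 + q.m and c2 < c1 + p.m)


def split_dataset(patches: Sequence[Patch], plan: SplitPlan
                  ) -> Dict[str, List[int]]:
    """Disjoint, exhaustive index partition into repr / finetune / test.

    ``random_patch`` shuffles patch indices and cuts at the exact fraction
    boundaries (sizes exact to +-1 patch). ``spatial_block`` assigns whole
    source images to pools: since sliding windows never cross image
    boundaries, no window in one pool shares a single source pixel with a
    window in another, at the price of pool sizes only approximating the
    fractions (granularity = patches per image).
    """
    plan.validate()
    n = len(patches)
    if n < plan.folds:
        raise ValueError(f"{n} patches cannot support {plan.folds} folds")
    rng = np.random.default_rng(plan.seed)
    if plan.strategy == "random_patch":
        order = rng.permutation(n)
        n_repr = int(round(plan.repr_fraction * n))
        n_ft = int(round(plan.finetune_fraction * n))
        return {
            "repr": [int(i) for i in order[:n_repr]],
            "finetune": [int(i) for i in order[n_repr:n_repr + n_ft]],
            "test": [int(i) for i in order[n_repr + n_ft:]],
        }
    # spatial_block: shuffle source images, fill test then finetune pools to
    # their patch-count targets, remainder to repr
    groups: Dict[str, List[int]] = {}
    for i, p in enumerate(patches):
        groups.setdefault(p.source_id, []).append(i)
    sources = sorted(groups)
    rng.shuffle(sources)
    n_test_target = plan.test_fraction * n
    n_ft_target = plan.finetune_fraction * n
    out: Dict[str, List[int]] = {"repr": [], "finetune": [], "test": []}
    for src in sources:
        if len(out["test"]) < n_test_target:
            out["test"].extend(groups[src])
        elif len(out["finetune"]) < n_ft_target:
            out["finetune"].extend(groups[src])
        else:
            out["repr"].extend(groups[src])
    return out


def save_patches(patches: Sequence[Patch], directory) -> List[str]:
    """Materialize patches as grayscale PNGs named by source and origin."""
    from pathlib import Path
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in patches:
        name = f"{p.source_id}_r{p.origin[0]:05d}_c{p.origin[1]:05d}.png"
        iio.imwrite(directory / name, np.asarray(p.pixels, dtype=np.uint8))
        paths.append(str(directory / name))
    return paths


def label_table(patches: Sequence[Patch], labels: Sequence[MultiLabel],
                splits: Dict[str, List[int]] | None = None) -> pd.DataFrame:
    """Tabular view: (source_id, row, col, kernel, byproduct, cell, surface,
    split, fold)."""
    split_of = {}
    if splits:
        for name, idxs in splits.items():
            for i in idxs:
                split_of[i] = name
    rows = []
    for i, (p, lab) in enumerate(zip(patches, labels)):
        rows.append({
            "source_id": p.source_id, "row": p.origin[0], "col": p.origin[1],
            "kernel": p.m, "byproduct": int(lab.byproduct),
            "cell": int(lab.cell), "surface": int(lab.surface),
            "split": split_of.get(i, ""), "fold": -1,
        })
    return pd.DataFrame(rows)
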